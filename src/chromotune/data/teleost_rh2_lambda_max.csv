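pigment_id,species,opsin,uniprot_accession,lambda_max_nm
zebrafish_Rh2-1,Danio rerio,Rh2-1,Q9W6A5,467
zebrafish_Rh2-2,Danio rerio,Rh2-2,Q8AYM8,476
zebrafish_Rh2-3,Danio rerio,Rh2-3,Q8AYM7,488
zebrafish_Rh2-4,Danio rerio,Rh2-4,Q9W6A6,505
zebrafish_Rh2-anc1,Danio rerio (ancestral),Rh2-anc1,,506
zebrafish_Rh2-anc2,Danio rerio (ancestral),Rh2-anc2,,474
zebrafish_Rh2-anc3,Danio rerio (ancestral),Rh2-anc3,,506
medaka_Rh2-A,Oryzias latipes,Rh2-A,P87366,452
medaka_Rh2-C,Oryzias latipes,Rh2-C,H2N0S5,492
guppy_Rh2-1,Poecilia reticulata,Rh2-1,Q0H3C4,516
guppy_Rh2-2,Poecilia reticulata,Rh2-2,Q0H3C5,476
cichlid_Rh2-B,Metriaclima zebra,Rh2-B,F8TJX3,484
cichlid_Rh2-Abeta,Metriaclima zebra,Rh2-Abeta,F8TJX5,519
cichlid_Rh2-Aalpha,Metriaclima zebra,Rh2-Aalpha,F8TJX4,528
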