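{
  "atom_names": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ",
                 "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9", "C10",
                 "C11", "C12", "C13", "C14", "C15", "C16", "C17", "C18", "C19", "C20"],
  "torsion_defs": {
    "Torsion 1":  ["C5", "C6", "C7", "C8"],
    "Torsion 2":  ["C6", "C7", "C8", "C9"],
    "Torsion 3":  ["C7", "C8", "C9", "C10"],
    "Torsion 4":  ["C8", "C9", "C10", "C11"],
    "Torsion 5":  ["C9", "C10", "C11", "C12"],
    "Torsion 6":  ["C10", "C11", "C12", "C13"],
    "Torsion 7":  ["C11", "C12", "C13", "C14"],
    "Torsion 8":  ["C12", "C13", "C14", "C15"],
    "Torsion 9":  ["C13", "C14", "C15", "NZ"],
    "Torsion 10": ["C14", "C15", "NZ", "CE"],
    "Torsion 11": ["C15", "NZ", "CE", "CD"],
    "Torsion 12": ["NZ", "CE", "CD", "CG"],
    "Torsion 13": ["CE", "CD", "CG", "CB"],
    "Torsion 14": ["CD", "CG", "CB", "CA"],
    "Torsion 15": ["C7", "C6", "C5", "C18"]
  },
  "angle_defs": {
    "Angle 1": ["C6", "C7", "C8"],
    "Angle 2": ["C10", "C11", "C12"],
    "Angle 3": ["CE", "NZ", "C15"],
    "Angle 4": ["C5", "C6", "C7"]
  },
  "ring_atoms": ["C1", "C2", "C3", "C4", "C5", "C6", "C16", "C17", "C18"],
  "profile_order": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ",
                    "C15", "C14", "C20", "C13", "C12", "C11", "C10", "C19", "C9",
                    "C8", "C7", "C6", "C18", "C5", "C4", "C3", "C2", "C1", "C16", "C17"]
}
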