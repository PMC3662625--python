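{
  "schema_version": "1.0",
  "description": "Strand-order sub-classes of the Rossmann-fold (fold type I) SAM-dependent MTase sheet. Keys are left-to-right strand-order permutations (strands numbered N->C); the slash key is the dual-domain arrangement with one sheet of each major class.",
  "entries": {
    "3214567": {"ligfold_id": "SAM_DM_Ia", "subclass": "Class Ia", "n_structures": 351},
    "6754123": {"ligfold_id": "SAM_DM_Ib", "subclass": "Class Ib", "n_structures": 321},
    "32145":   {"ligfold_id": "SAM_DM_Ic", "subclass": "Class Ic", "n_structures": 2},
    "54123":   {"ligfold_id": "SAM_DM_Id", "subclass": "Class Id", "n_structures": 19},
    "564312":  {"ligfold_id": "SAM_DM_Ie", "subclass": "Class Ie", "n_structures": 29},
    "654321":  {"ligfold_id": "SAM_DM_If", "subclass": "Class If", "n_structures": 2},
    "1762354": {"ligfold_id": "SAM_DM_Ig", "subclass": "Class Ig", "n_structures": 10},
    "7645321": {"ligfold_id": "SAM_DM_Ih", "subclass": "Class Ih", "n_structures": 1},
    "7654123": {"ligfold_id": "SAM_DM_Ii", "subclass": "Class Ii", "n_structures": 12},
    "17865234": {"ligfold_id": "SAM_DM_Ij", "subclass": "Class Ij", "n_structures": 1},
    "5671432": {"ligfold_id": "SAM_DM_Ik", "subclass": "Class Ik", "n_structures": 2},
    "6754123/3214567": {"ligfold_id": "SAM_DM_Il", "subclass": "Class Il", "n_structures": 1},
    "3421567": {"ligfold_id": "SAM_DM_Im", "subclass": "Class Im", "n_structures": 1},
    "34215687": {"ligfold_id": "SAM_DM_In", "subclass": "Class In", "n_structures": 4}
  }
}
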