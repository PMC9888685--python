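{
  "description": "Race-by-covariate cross-tabulations for the Florida Cancer Data System endometrial cancer cohort (female NHW/NHB cases, 2005-2014; n = 13,506). Row 0 = WNH, row 1 = BNH.",
  "notes": "The surgery BNH row (348 / 1210) duplicates the chemo BNH row in the published summary and is inconsistent with the separately reported 'No hysterectomy' log-odds coefficient (0.69756); surgery-derived coefficients are therefore excluded from validation and this table is retained for completeness only.",
  "tables": {
    "age_quartile": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["21-57", "58-64", "65-72", "73-99"],
      "counts": [[3198, 2912, 2949, 2889], [455, 437, 414, 252]]
    },
    "grade": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["1", "2", "3", "4"],
      "counts": [[5260, 3915, 2362, 411], [491, 410, 556, 101]]
    },
    "stage": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["1", "2", "3", "4"],
      "counts": [[8588, 1119, 1675, 566], [968, 164, 276, 150]]
    },
    "surgery": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["Hysterectomy", "No hysterectomy"],
      "counts": [[11582, 366], [348, 1210]]
    },
    "chemo": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["Chemo", "No chemo"],
      "counts": [[1744, 10204], [348, 1210]]
    },
    "insurance": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["Insured, NOS", "Medicaid", "Medicare", "Military/VA/Tricare/IHS", "Not insured", "Private"],
      "counts": [[561, 305, 5621, 229, 436, 4796], [48, 120, 640, 33, 109, 608]]
    },
    "marital": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["Divorced", "Married", "Separated", "Single", "Unmarried or Domestic Partner", "Widowed"],
      "counts": [[1307, 6679, 73, 1907, 8, 1974], [205, 574, 31, 463, 0, 285]]
    },
    "histology": {
      "row_labels": ["WNH", "BNH"],
      "col_labels": ["Carcinosarcoma", "Endometrioid Adenocarcinoma", "Serous", "Undifferentiated"],
      "counts": [[219, 11103, 613, 13], [77, 1280, 199, 2]]
    }
  }
}
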