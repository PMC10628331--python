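{
  "format_version": 1,
  "description": "Critical value list (numeric ranges only): per-item low/high thresholds, both inclusive. A result is critical when value <= low or value >= high.",
  "rules": [
    {"item_code": "glucose", "name": "Glucose", "category": "Chemistry", "low": 50, "high": 450, "units": "mg/dL"},
    {"item_code": "creatinine", "name": "Creatinine", "category": "Chemistry", "low": null, "high": 3, "units": "mg/dL"},
    {"item_code": "total_bilirubin", "name": "Total bilirubin", "category": "Chemistry", "low": null, "high": 5, "units": "mg/dL"},
    {"item_code": "alkaline_phosphatase", "name": "Alkaline phosphatase", "category": "Chemistry", "low": null, "high": 1000, "units": "IU/L"},
    {"item_code": "lactate_dehydrogenase", "name": "Lactate dehydrogenase", "category": "Chemistry", "low": null, "high": 1000, "units": "IU/L"},
    {"item_code": "aspartate_aminotransferase", "name": "Aspartate aminotransferase", "category": "Chemistry", "low": null, "high": 1000, "units": "IU/L"},
    {"item_code": "alanine_aminotransferase", "name": "Alanine aminotransferase", "category": "Chemistry", "low": null, "high": 1000, "units": "IU/L"},
    {"item_code": "amylase", "name": "Amylase", "category": "Chemistry", "low": null, "high": 1000, "units": "IU/L"},
    {"item_code": "creatine_kinase", "name": "Creatine kinase", "category": "Chemistry", "low": null, "high": 5000, "units": "IU/L"},
    {"item_code": "calcium", "name": "Calcium", "category": "Chemistry", "low": 6, "high": 12, "units": "mg/dL"},
    {"item_code": "sodium", "name": "Sodium", "category": "Chemistry", "low": 119, "high": 160, "units": "mmol/L"},
    {"item_code": "potassium", "name": "Potassium", "category": "Chemistry", "low": 2.5, "high": 6, "units": "mmol/L"},
    {"item_code": "white_blood_cell_count", "name": "White blood cell count", "category": "Hematology", "low": 2, "high": 20, "units": "10^3/mm^3"},
    {"item_code": "hemoglobin", "name": "Hemoglobin", "category": "Hematology", "low": 8, "high": 17, "units": "g/dL"},
    {"item_code": "platelet_count", "name": "Platelet count", "category": "Hematology", "low": 50, "high": 700, "units": "10^3/mm^3"},
    {"item_code": "neutrophil_count", "name": "Neutrophil count", "category": "Hematology", "low": 0.5, "high": null, "units": "10^3/mm^3"},
    {"item_code": "lymphocyte_rate", "name": "Lymphocyte rate", "category": "Hematology", "low": null, "high": 70, "units": "%"},
    {"item_code": "atypical_lymphocyte_rate", "name": "Atypical lymphocyte rate", "category": "Hematology", "low": null, "high": 10, "units": "%"},
    {"item_code": "eosinocyte_rate", "name": "Eosinocyte rate", "category": "Hematology", "low": null, "high": 20, "units": "%"},
    {"item_code": "pt_inr", "name": "PT-INR", "category": "Coagulation", "low": null, "high": 4, "units": ""},
    {"item_code": "activated_partial_thromboplastin_time", "name": "Activated partial thromboplastin time", "category": "Coagulation", "low": null, "high": 225, "units": "seconds"},
    {"item_code": "fibrinogen", "name": "Fibrinogen", "category": "Coagulation", "low": 100, "high": null, "units": "mg/dL"}
  ]
}
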