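{
  "systems": {
    "loinc": "http://loinc.org",
    "phase_relationship": "http://hl7.org/fhir/uv/genomics-reporting/CodeSystem/seq-phase-relationship",
    "observation_category": "http://terminology.hl7.org/CodeSystem/observation-category",
    "local": "urn:vcf2report:codes"
  },
  "report_code": {"code": "81247-9", "display": "Master HL7 genetic variant reporting panel"},
  "variant_code": {"code": "69548-6", "display": "Genetic variant assessment"},
  "region_studied_code": {"code": "53041-0", "display": "DNA region of interest panel"},
  "phase_code": {"code": "82120-7", "display": "Allelic phase"},
  "variant_present": {"code": "LA9633-4", "display": "Present"},
  "variant_absent": {"code": "LA9634-2", "display": "Absent"},
  "components": {
    "reference_sequence": {"code": "48013-7", "display": "Genomic reference sequence ID"},
    "reference_allele": {"code": "69547-8", "display": "Genomic ref allele"},
    "alternate_allele": {"code": "69551-0", "display": "Genomic alt allele"},
    "exact_position": {"code": "81254-5", "display": "Variant exact start-end"},
    "allelic_state": {"code": "53034-5", "display": "Allelic state"},
    "genomic_source_class": {"code": "48002-0", "display": "Genomic source class"},
    "coordinate_system": {"code": "92822-6", "display": "Genomic coordinate system"},
    "ranges_examined": {"code": "51959-5", "display": "Range(s) of DNA sequence examined"},
    "uncallable_region": {"code": "uncallable-region", "display": "Uncallable subregion", "system": "local"}
  },
  "allelic_states": {
    "heterozygous": {"code": "LA6706-1", "display": "Heterozygous"},
    "homozygous": {"code": "LA6705-3", "display": "Homozygous"},
    "hemizygous": {"code": "LA6707-9", "display": "Hemizygous"},
    "homoplasmic": {"code": "LA6704-6", "display": "Homoplasmic"},
    "heteroplasmic": {"code": "LA6703-8", "display": "Heteroplasmic"}
  },
  "genomic_source_germline": {"code": "LA6683-2", "display": "Germline"},
  "coordinate_system_1_based": {"code": "LA30102-0", "display": "1-based character counting"},
  "phase_relations": {
    "CIS": {"code": "Cis", "display": "Cis", "system": "phase_relationship"},
    "TRANS": {"code": "Trans", "display": "Trans", "system": "phase_relationship"}
  }
}
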