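{
 "gene_log_hr": {
  "MAP3K1": {
   "BCSS": -0.4
  },
  "PIK3CA": {
   "BCSS": -0.3
  },
  "TP53": {
   "BCSS": 0.5
  }
 },
 "mpmb_correction": 1.3,
 "sample_purity": {
  "S0000": 0.6545776733988851,
  "S0001": 0.498367681908381,
  "S0002": 0.8378646444255621,
  "S0003": 0.47280554311717726,
  "S0004": 0.7295708632459318,
  "S0005": 0.5586159579927451,
  "S0006": 0.8882324540458464,
  "S0007": 0.5908500999189269,
  "S0008": 0.5549160523048179,
  "S0009": 0.4162451475812815,
  "S0010": 0.7567259561842561,
  "S0011": 0.5720231557265016
 },
 "variant_labels": {
  "S0000|1|1001425|T|C": "somatic",
  "S0000|2|2000931|A|T": "germline",
  "S0000|3|3003000|T|A": "somatic",
  "S0000|3|3004340|C|T": "artifact",
  "S0002|1|1001851|C|A": "somatic",
  "S0002|3|3002891|A|G": "artifact",
  "S0002|3|3003949|G|A": "germline",
  "S0002|3|3004340|C|T": "artifact",
  "S0003|1|1000993|AGCT|A": "somatic",
  "S0003|2|2000124|G|A": "germline",
  "S0003|3|3000058|G|C": "germline",
  "S0003|3|3002891|A|G": "artifact",
  "S0003|3|3004340|C|T": "artifact",
  "S0004|1|1003015|G|T": "somatic",
  "S0004|2|2000033|A|T": "somatic",
  "S0004|3|3002891|A|G": "artifact",
  "S0005|3|3000058|G|C": "germline",
  "S0005|3|3004340|C|T": "artifact",
  "S0006|1|1002226|AT|A": "somatic",
  "S0006|2|2000124|G|A": "germline",
  "S0006|3|3002891|A|G": "artifact",
  "S0006|3|3003949|G|A": "germline",
  "S0007|3|3004340|C|T": "artifact",
  "S0008|1|1003039|G|C": "somatic",
  "S0008|2|2000144|C|T": "somatic",
  "S0008|2|2000835|C|G": "germline",
  "S0009|3|3000058|G|C": "germline",
  "S0009|3|3001458|C|G": "somatic",
  "S0009|3|3004340|C|T": "artifact",
  "S0010|2|2000124|G|A": "germline",
  "S0010|2|2000369|G|T": "somatic",
  "S0010|3|3000058|G|C": "germline",
  "S0011|3|3000058|G|C": "germline"
 }
}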