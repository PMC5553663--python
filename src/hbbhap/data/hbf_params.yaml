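# Default per-diplotype fetal hemoglobin (HbF, % of total hemoglobin)
# distribution parameters and cohort composition for the synthetic
# cohort generator.  Values are the CSSCD SNP-based classification
# summaries (916 African-American sickle cell anemia patients): n is
# used as the relative diplotype frequency weight, mean/sd parameterize
# a Normal truncated below at 0.  AI/AI comes from the Eastern-Province
# Saudi cohort (n=30), the only cohort where that diplotype occurs.
# "default" is the fallback for diplotypes without a cohort estimate
# (adult BEN/CAR/CAM-background haplotypes run 5-7% HbF).
classes:
  BEN/BEN: {n: 379, mean: 6.39, sd: 5.14}
  BEN/CAR: {n: 261, mean: 7.04, sd: 6.77}
  BEN/SEN: {n: 116, mean: 7.99, sd: 5.32}
  BEN/CAM: {n: 53, mean: 5.33, sd: 5.19}
  CAR/CAR: {n: 41, mean: 5.59, sd: 3.90}
  CAR/SEN: {n: 24, mean: 8.91, sd: 7.59}
  CAR/CAM: {n: 18, mean: 3.96, sd: 3.24}
  SEN/SEN: {n: 13, mean: 8.74, sd: 4.35}
  SEN/CAM: {n: 9, mean: 8.61, sd: 6.02}
  CAM/CAM: {n: 1, mean: 7.00, sd: 0.0}
  CAR/AI: {n: 1, mean: 16.10, sd: 0.0}
  AI/AI: {n: 30, mean: 18.03, sd: 5.39}
default: {mean: 7.0, sd: 5.0}
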