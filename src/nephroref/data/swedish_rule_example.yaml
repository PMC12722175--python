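# EXAMPLE Swedish-style referral rule -- NON-AUTHORITATIVE PLACEHOLDER.
# The actual national referral thresholds are published in clinical guidance
# that is not reproduced in this repository; these clauses only illustrate
# the age/eGFR/albuminuria threshold structure such criteria use.  Edit this
# file (or supply your own via rules.load_rule_config) with transcribed
# thresholds before drawing any real-world conclusion.
name: swedish_example
provenance: placeholder illustrating fixed age/eGFR/albuminuria thresholds
clauses:
  # severe loss of filtration at any age
  - egfr: ["<", 30]
  # moderate loss in the (non-elderly) young, where lifetime risk is larger
  - egfr: ["<", 45]
    age: ["<", 65]
  # severe albuminuria
  - acr_mgg: [">=", 300]
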