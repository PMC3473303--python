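# Baseline scenario of the RCT trust game.
# Utilities are on a 0-100 scale; u* are the patient's, v* the researcher's,
# indexed: 1 experimental success, 2 experimental failure, 3 standard
# success, 4 standard failure.
#
# Transcription notes on the published parameter table this mirrors:
#   - the patient's standard-success range is printed there as "(50-1100)";
#     read as (50-100), a typo, since utilities live on the 0-100 scale;
#   - the Monte Carlo summary's abuse-row total is printed as "50.2%" but
#     the counts (59,222 / 100,000) give 59.2%, an arithmetic typo.
payoffs:
  u1: 90.0
  u2: 16.3
  u3: 84.0
  u4: 16.9
  v1: 95.0
  v2: 54.0
  v3: 70.0
  v4: 44.0
probabilities:
  e: 0.41   # experimental-treatment success
  s: 0.59   # standard-treatment success
  r: 0.5    # randomization to the experimental arm
  p: 0.5    # researcher honors trust
psych:
  regret: 0.2
  guilt: 0.2
label: table1_baseline
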