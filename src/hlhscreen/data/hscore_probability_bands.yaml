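# HScore -> probability-of-sHLH band labels (percent).
#
# Anchored by the observed (score, band) pairs in the study cohort:
#   174, 177 -> "54";  181 -> "70";  193, 194 -> "80";  202, 205 -> "88";
#   227 -> "96";  241 -> "99";  267, 291, 321 -> ">99".
# Boundaries BETWEEN anchored scores are interpolated at the midpoint and
# flagged; only the anchored pairs are guaranteed.  Scores below the lowest
# band fall into the "<54" sentinel band.
bands:
  - {lo: null, hi: 168, label: "<54", interpolated: true}
  - {lo: 169, hi: 179, label: "54", interpolated: true}
  - {lo: 180, hi: 187, label: "70", interpolated: true}
  - {lo: 188, hi: 198, label: "80", interpolated: true}
  - {lo: 199, hi: 216, label: "88", interpolated: true}
  - {lo: 217, hi: 234, label: "96", interpolated: true}
  - {lo: 235, hi: 253, label: "99", interpolated: true}
  - {lo: 254, hi: null, label: ">99", interpolated: true}
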