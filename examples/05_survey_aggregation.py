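"""Aggregate the seven-scanner survey tables.

The `SURVEY_*` presets hold measured per-scanner metric values from a
five-center ¹⁶⁶Ho image-quality survey.  The aggregation routines reproduce
the headline cross-scanner comparisons.
"""

from hospect.metrics import (percent_difference_between_groups,
                             percent_difference_per_scanner, records_to_frame,
                             summarize)
from hospect.presets import (SURVEY_CRC_MEAN, SURVEY_SCANNER_VENDOR,
                             SURVEY_SENSITIVITY_CPS_PER_MBQ, dew_cov, tew_cov)

# vendor gap in photopeak sensitivity
recs = [{"scanner": s, "vendor": SURVEY_SCANNER_VENDOR[s], "method": "acq",
         "metric": "sens", "value": row["photopeak"]}
        for s, row in SURVEY_SENSITIVITY_CPS_PER_MBQ.items()]
df = records_to_frame(recs)
gap = percent_difference_between_groups(df, "sens", "vendor", "GE", "Siemens")
print(f"GE photopeak sensitivity sits {-gap:.1f}% below the Siemens mean")
print(summarize(df).to_string(index=False))

# TEW vs DEW on the largest sphere
dew, tew = SURVEY_CRC_MEAN["dew"][37], SURVEY_CRC_MEAN["tew"][37]
print(f"\n37 mm sphere CRC: TEW {tew:.2f} vs DEW {dew:.2f} "
      f"({100 * (tew - dew) / dew:+.1f}%)")

# DEW vs TEW noise, paired per scanner
recs = []
for s in SURVEY_SCANNER_VENDOR:
    recs.append({"scanner": s, "method": "dew", "metric": "cov",
                 "value": dew_cov(s)})
    recs.append({"scanner": s, "method": "tew", "metric": "cov",
                 "value": tew_cov(s)})
red = percent_difference_per_scanner(records_to_frame(recs), "cov",
                                     "dew", "tew")
print(f"DEW lowers the cylinder COV by {-red:.1f}% on average "
      f"(per-scanner pairing)")
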