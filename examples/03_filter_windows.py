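"""Remove problematic genomic windows before interpretation.

Windows overlapping simple repeats or a blacklist, with low
mappability, or with unstable molar amounts between replicates are
dropped, each criterion attributed in order.
"""

import numpy as np
import pandas as pd

from medipspike import FilterConfig, apply_filters, make_windows, replicate_sd

track = make_windows({"chr1": 3000})
rng = np.random.default_rng(0)
rep1, rep2 = track.copy(), track.copy()
base = rng.uniform(0, 1e-3, len(track))
rep1.windows["amount_pmol"] = base
rep2.windows["amount_pmol"] = base + rng.normal(0, 1e-5, len(track))
rep2.windows.loc[4, "amount_pmol"] += 0.2  # an irreproducible window

track.windows["min_mappability"] = 1.0
track.windows.loc[3, "min_mappability"] = 0.4

blacklist = pd.DataFrame([("chr1", 0, 600)],
                         columns=["chrom", "start", "end"])
sd = replicate_sd([rep1, rep2])
surviving, report = apply_filters(
    track, sd, FilterConfig(blacklist_bed=blacklist)
)
print(f"windows in          : {len(track)}")
print(f"removal report      : {report}")
print(f"max surviving SD    : {sd[(surviving.windows.start // 300)].max():.2g} pmol")
# Windows failing any criterion are excluded so that downstream molar
# amounts come only from uniquely mappable, reproducible regions.
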