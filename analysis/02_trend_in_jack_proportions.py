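"""Long-term trend in cohort jack proportions and abundances.

Reconstructs the brood table from results/data/, then fits the biased random
walk to (i) logit jack proportions, (ii) log jack abundance and (iii) log
nonjack abundance by brood year, reporting the posterior drift (trend per
year) for each.  Writes results/trend_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from jackrun.ages import brood_summaries, read_brood_table
from jackrun.infer import SamplerConfig, sample_posterior
from jackrun.models import RWTrendModel
from jackrun.report import summarize

ROOT = Path(__file__).resolve().parents[1] / "results"
SAMPLER = SamplerConfig(n_chains=4, n_iterations=2000, seed=1)


def main() -> None:
    brood = read_brood_table(ROOT / "data" / "brood_table.csv")
    summ = brood_summaries(brood)
    summ = summ[~summ["undefined"]]
    p = summ["jack_proportion"].to_numpy()
    series = {
        "logit_jack_proportion": np.log(p) - np.log1p(-p),
        "log_jack_abundance": np.log(summ["jack_abundance"].to_numpy()),
        "log_nonjack_abundance": np.log(summ["nonjack_abundance"].to_numpy()),
    }
    rows = []
    for name, values in series.items():
        draws = sample_posterior(RWTrendModel(values), SAMPLER)
        s = summarize(draws, ["u", "sigma_error"]).assign(series=name)
        rows.append(s)
        u = s[s.parameter == "u"].iloc[0]
        print(f"{name}: drift u median {u['median']:+.3f}/yr "
              f"(95% CI {u['q2.5']:+.3f} to {u['q97.5']:+.3f})")
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(ROOT / "trend_summary.csv", index=False)
    print(f"wrote {ROOT / 'trend_summary.csv'}")


if __name__ == "__main__":
    main()
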