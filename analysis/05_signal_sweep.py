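"""Recovery score as a function of trophic signal strength.

Sweeps the propagation correlation over {0, 0.5, 0.9} with 10 replicate
ecosystems each, showing that link recovery rises from chance (0.5) as
prey responses propagate more strongly to their consumers.  Writes
results/signal_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from trophinet import (
    AnalysisConfig,
    SyntheticConfig,
    build_ensemble,
    build_observations,
    generate,
    recovery_score,
)
from trophinet.background_knowledge import build_cooccurrence

ROOT = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    rows = []
    for pc in (0.0, 0.5, 0.9):
        scores = []
        for seed in range(1, 11):
            cfg = SyntheticConfig(propagation_correlation=pc, rng_seed=seed)
            eco = generate(cfg)
            if not eco.true_links:
                continue
            acfg = AnalysisConfig(rng_seed=seed)
            obs = build_observations(eco.counts, acfg)
            cooc = build_cooccurrence(eco.points, eco.counts)
            ens = build_ensemble(obs, eco.traits, cooc, acfg)
            scores.append(recovery_score(ens, eco.true_links, eco.traits))
        rows.append({
            "propagation_correlation": pc,
            "n_replicates": len(scores),
            "mean_recovery": round(float(np.mean(scores)), 4),
            "sd_recovery": round(float(np.std(scores, ddof=1)), 4),
        })
        print(f"rho = {pc:3.1f}: mean recovery {rows[-1]['mean_recovery']:.3f} "
              f"(sd {rows[-1]['sd_recovery']:.3f}, n={len(scores)})")
    ROOT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "signal_sweep.csv", index=False)

if __name__ == "__main__":
    main()
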