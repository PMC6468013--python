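#!/usr/bin/env python
"""Score the analysis chain against the generator's ground truth.

Runs the three evaluation experiments — seasonal-parameter recovery, tactic
classification, stopover detection — and writes results/evaluation.json.
"""

import json
import warnings
from pathlib import Path

from herdtrack import evaluation

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore")
    rec = evaluation.recovery_experiment(n=200, noise_sd_km=0.5, seed=SEED)
    biases = {
        p: 100.0 * evaluation.relative_bias(rec, p) for p in ("delta", "theta", "phi")
    }
    cls = evaluation.classification_experiment(n=100, seed=SEED)
    sc = evaluation.stopover_benchmark(n_tracks=50, seed=SEED)
    out = {
        "parameter_bias_pct": {k: round(v, 2) for k, v in biases.items()},
        "classification_accuracy": round(float(cls["correct"].mean()), 3),
        "stopover_recall": round(sc.recall, 3),
        "stopover_precision": round(sc.precision, 3),
        "n": {"recovery": len(rec), "classification": len(cls), "dwells": sc.n_true},
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "evaluation.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
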