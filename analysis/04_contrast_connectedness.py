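#!/usr/bin/env python
"""Contrast manipulations and connected dot pairs.

1. mixed black/white items vs all-black (signed-deviation analysis):
   mixing raises mean power slightly (~1.6%);
2. per-item contrast drawn from a narrow (0.1) vs wide (0.85) range
   centered on 0.5: the mean rises ~10% while the 95% interval of
   per-display power widens several-fold;
3. dot pairs with bars or illusory-contour inducers: bars raise and
   inducers lower power, and rotating the element to break the
   connection leaves power unchanged -- the statistic cannot explain
   the connectedness illusion.

Writes contrast_experiments.json and connectedness.csv.
"""

import json
from pathlib import Path

import numpy as np

from numspec.protocols import (
    connectedness_experiment,
    contrast_range_experiment,
    mixed_black_white_contrast,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    mixed = mixed_black_white_contrast(n_displays=80,
                                       rng=np.random.default_rng(21))
    print(f"mixed vs black: +{mixed['pct_increase']:.2f}% mean power")

    spread = contrast_range_experiment(n_displays=80,
                                       rng=np.random.default_rng(22))
    print(f"contrast range 0.1 -> 0.85: mean +{spread['mean_pct_increase']:.1f}%, "
          f"95% interval width +{spread['ci_width_pct_increase']:.0f}%")

    payload = {
        "mixed_vs_black_pct": mixed["pct_increase"],
        "mean_black": mixed["mean_black"],
        "mean_mixed": mixed["mean_mixed"],
        "ci_width_pct_increase": spread["ci_width_pct_increase"],
        "mean_pct_increase": spread["mean_pct_increase"],
    }
    (OUT / "contrast_experiments.json").write_text(
        json.dumps(payload, indent=2))

    conn = connectedness_experiment()
    conn.to_csv(OUT / "connectedness.csv", index=False)
    p = conn.set_index("connection")["power"]
    print("connectedness:", ", ".join(f"{k}={v:.3f}" for k, v in p.items()))
    print(f"wrote results to {OUT}")


if __name__ == "__main__":
    main()
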