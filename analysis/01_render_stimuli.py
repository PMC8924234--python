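#!/usr/bin/env python
"""Render an example gallery of the four stimulus configurations.

Writes one PNG and one JSON spec per (configuration, numerosity) for
numerosities 1-7 and the 20-item baseline, mirroring the experimental
display families: constant total area, constant item size, constant
total perimeter, and the high-density grouping.
"""

from pathlib import Path

import numpy as np

from numspec.io import save_display_spec, save_image_png
from numspec.stimuli import Configuration, make_configuration_display, render

OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main() -> None:
    rng = np.random.default_rng(2024)
    OUT.mkdir(parents=True, exist_ok=True)
    count = 0
    for config in (Configuration.CONSTANT_AREA, Configuration.CONSTANT_SIZE,
                   Configuration.CONSTANT_PERIMETER, Configuration.HIGH_DENSITY):
        for n in [*range(1, 8), 20]:
            spec = make_configuration_display(config, n, rng=rng)
            stem = f"{config.value}_n{n:02d}"
            save_image_png(render(spec), OUT / f"{stem}.png")
            save_display_spec(spec, OUT / f"{stem}.json")
            count += 1
    print(f"rendered {count} example displays to {OUT}")


if __name__ == "__main__":
    main()
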