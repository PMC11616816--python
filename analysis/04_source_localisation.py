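"""sLORETA dipole recovery and group source contrasts on synthetic gains.

First verifies the zero-localisation-error property of the standardised
minimum-norm inverse on noiseless single-dipole data (50 random dipoles,
32 channels, 200 sources), then simulates two groups of subjects whose
topographies differ in a block of sources and shows that the two-sample
permutation t-test with Benjamini-Hochberg control (alpha = .01) and the
minimum-cluster-size-5 rule recovers the affected block.

Finding (seed 3): 50/50 dipoles localise exactly; the injected 10-source
power shift is recovered with no false positives outside the block.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from refback.sources import (
    compare_group_sources,
    make_synthetic_leadfield,
    sloreta_inverse,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rng = np.random.default_rng(3)
    lf = make_synthetic_leadfield(32, 200, seed=3)
    lam = 1e-8 * np.trace(lf.matrix @ lf.matrix.T) / lf.n_channels

    hits = 0
    for _ in range(50):
        i = int(rng.integers(lf.n_sources))
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        d = lf.matrix[:, 3 * i : 3 * i + 3] @ e
        hits += int(np.argmax(sloreta_inverse(lf, d, lam=lam).power) == i)
    print(f"zero-localisation check: {hits}/50 dipoles recovered exactly")

    # group contrast: power shifted at sources 60..69 in group A
    n_subj, n_src = 12, lf.n_sources
    a = rng.normal(1.0, 0.15, size=(n_subj, n_src)) ** 2
    b = rng.normal(1.0, 0.15, size=(n_subj, n_src)) ** 2
    a[:, 60:70] += 4.0
    contrast = compare_group_sources(a, b, n_perm=2000, seed=4)

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"quantity": "dipole_recovery_rate", "value": hits / 50}]
    ).to_csv(OUT / "source_localisation_summary.csv", index=False)
    contrast.to_csv(OUT / "source_group_contrast.csv", index=False)

    kept = contrast[contrast["kept"]]
    print(
        f"group contrast: {len(kept)} sources kept "
        f"(indices {kept['source'].min()}..{kept['source'].max()})"
    )


if __name__ == "__main__":
    main()
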