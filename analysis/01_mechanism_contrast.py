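"""Predict how GDP-tubulin affects plus- vs minus-end growth under the two
nucleotide mechanisms.

Runs mixed-nucleotide simulations (1 uM tubulin, 0-20% GDP-tubulin in 5%
steps) for both ends under the self-acting and interface-acting mechanisms
with illustrative parameters, and writes the replicate-level tables under
results/.  The signature to look for: minus-end curves are identical under
the two mechanisms (same random numbers, same rates), while plus-end growth
falls disproportionately under the interface-acting mechanism.
"""

import sys
from pathlib import Path

import pandas as pd

from mtgrowth import RunConfig, SimProtocol, run_figure_pipeline

OUT = Path("results/mechanism_contrast")


def main(seed: int = 1) -> None:
    config = RunConfig(
        protocol=SimProtocol(duration=600.0, n_replicates=50),
        seed=seed,
        out_dir=str(OUT),
    )
    summary = run_figure_pipeline("mechanism_contrast", config)

    print("\nNormalized growth (rate / rate at 0% GDP):")
    for name in ("plus_self_acting", "plus_interface_acting", "minus_self_acting"):
        df = pd.DataFrame(summary[name])
        norm = df["rate_nm_s_mean"] / df["rate_nm_s_mean"].iloc[0]
        print(f"  {name:24s}", " ".join(f"{v:.2f}" for v in norm))
    print(
        "\nMinus-end tables are identical under both mechanisms; the"
        " interface-acting plus-end falls fastest — the testable contrast."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
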