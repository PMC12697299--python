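#!/usr/bin/env python
"""D-periodic-spacing recovery across all eight experimental groups.

For each group the full imaging design (6 mice x 5 sites, 10 fibrils per
site, 512 px over the 5 um field) is simulated with the published group
mean +/- SD as generative truth, then flattened, segmented, traced and
measured.  Writes results/dspacing_recovery.csv and prints the recovery
table: every group mean should come back within ~1 nm of its generative
value, reproducing the published patterns (aged > adult at 0 N by ~10%;
adult-HLU increasing ~7% from 0 N to 4 N).
"""

import warnings
from pathlib import Path

import pandas as pd

from mcfnano import GROUP_LABELS, default_group_params, percent_difference
from mcfnano.pipeline import recover_group_dspacing

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260919


def main() -> None:
    rows = []
    for label in GROUP_LABELS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, n, table = recover_group_dspacing(label, SEED)
        params = default_group_params(label)
        rows.append(
            {
                "group": label,
                "d_generative_nm": params.d_mean,
                "d_recovered_nm": round(mean, 2),
                "delta_nm": round(mean - params.d_mean, 2),
                "sd_recovered_nm": round(table.d_spacing_nm.std(ddof=1), 2),
                "n_fibrils": n,
            }
        )
        print(f"{label:18s} truth {params.d_mean:5.1f}  "
              f"recovered {mean:6.2f} nm  (n={n})")
    out = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "dspacing_recovery.csv", index=False)

    rec = dict(zip(out.group, out.d_recovered_nm))
    print("\naged vs adult control 0N: "
          f"{percent_difference(rec['aged-control-0N'], rec['adult-control-0N']):.1f}% larger")
    print("adult-HLU 0N -> 4N: "
          f"{percent_difference(rec['adult-HLU-4N'], rec['adult-HLU-0N']):.1f}% increase")
    print(f"table -> {OUT / 'dspacing_recovery.csv'}")


if __name__ == "__main__":
    main()
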