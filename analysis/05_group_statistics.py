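#!/usr/bin/env python
"""Statistical surface over the recovered measurements.

Re-uses the tables written by 02 and 04 (running them first if needed is
up to the caller; this script recomputes a compact two-group comparison
from scratch so it stands alone): adult-control vs aged-control at 0 N.
Emits mean +/- SD summaries, the Kolmogorov-Smirnov distance between the
D-spacing distributions, Holm-Sidak-adjusted pairwise Welch comparisons,
and the derived percent difference / fold change that summarize the
age contrast.
"""

import warnings
from pathlib import Path

import pandas as pd

from mcfnano import (
    fold_change,
    holm_sidak,
    ks_two_sample,
    percent_difference,
    summarize,
)
from mcfnano.pipeline import recover_group_dspacing, recover_group_modulus
from mcfnano.stats import welch_t_pvalue

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260919


def main() -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, d_adult = recover_group_dspacing("adult-control-0N", SEED)
        _, _, d_aged = recover_group_dspacing("aged-control-0N", SEED)
        _, _, e_adult = recover_group_modulus("adult-control-0N", SEED)
        _, _, e_aged = recover_group_modulus("aged-control-0N", SEED)

    summaries = pd.DataFrame(
        s.__dict__
        for s in (
            summarize(d_adult.d_spacing_nm, "adult-control", "0N",
                      "d_spacing_nm"),
            summarize(d_aged.d_spacing_nm, "aged-control", "0N",
                      "d_spacing_nm"),
            summarize(e_adult[e_adult.converged].E_GPa, "adult-control",
                      "0N", "modulus_GPa"),
            summarize(e_aged[e_aged.converged].E_GPa, "aged-control", "0N",
                      "modulus_GPa"),
        )
    )
    print(summaries.round(3).to_string(index=False))

    ks = ks_two_sample(d_adult.d_spacing_nm, d_aged.d_spacing_nm)
    print(f"\nK-S on D-spacing distributions: D = {ks.D:.3f}, p = {ks.p:.2e}")

    p_raw = [
        welch_t_pvalue(d_adult.d_spacing_nm, d_aged.d_spacing_nm),
        welch_t_pvalue(
            e_adult[e_adult.converged].E_GPa, e_aged[e_aged.converged].E_GPa
        ),
    ]
    p_adj = holm_sidak(p_raw)
    pairwise = pd.DataFrame(
        {
            "comparison": ["adult vs aged 0N (D-spacing)",
                           "adult vs aged 0N (modulus)"],
            "p_raw": p_raw,
            "p_holm_sidak": p_adj,
            "significant": p_adj <= 0.05,
        }
    )
    print("\n" + pairwise.to_string(index=False))

    d_pct = percent_difference(
        d_aged.d_spacing_nm.mean(), d_adult.d_spacing_nm.mean()
    )
    e_fold = fold_change(
        e_aged[e_aged.converged].E_GPa.mean(),
        e_adult[e_adult.converged].E_GPa.mean(),
    )
    print(f"\naged D-spacing is {d_pct:.1f}% larger; "
          f"aged modulus is {e_fold:.2f}-fold higher")

    OUT.mkdir(exist_ok=True)
    summaries.to_csv(OUT / "group_summaries.csv", index=False)
    pairwise.to_csv(OUT / "group_pairwise.csv", index=False)
    pd.DataFrame([{"comparison": "adult vs aged control 0N",
                   "metric": "d_spacing_nm", "D": ks.D, "p": ks.p,
                   "n1": ks.n1, "n2": ks.n2}]).to_csv(
        OUT / "group_ks.csv", index=False
    )
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
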