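#!/usr/bin/env python
"""Simulate a demonstration cohort and write it to disk.

Generates two mice x two sites for each of the four 0 N / 4 N control
groups — AFM image pairs (amplitude + height TIFF with YAML sidecars),
per-indent force-curve TSVs, truth tables and a manifest — under
results/synthetic/.  The full-scale design (6 mice x 5 sites x 8 groups)
is what the tests and acceptance run; this scaled copy exists so the file
formats can be inspected by hand.
"""

from pathlib import Path

from mcfnano import CurveSpec, ImageSpec, ProbeParams, default_group_params
from mcfnano.synthgen import simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    groups = [
        default_group_params(label, n_mice=2, sites_per_mouse=2,
                             indents_per_site=5)
        for label in (
            "adult-control-0N", "adult-control-4N",
            "aged-control-0N", "aged-control-4N",
        )
    ]
    ds = simulate_dataset(
        groups,
        ImageSpec(n_pixels=512),
        CurveSpec(n_samples=4000),
        ProbeParams(),
        seed=20260919,
        outdir=OUT,
        keep_in_memory=False,
    )
    print(f"wrote {len(ds.manifest)} sites to {OUT}")
    print(f"  fibril truth records: {len(ds.truth.fibrils)}")
    print(f"  curve truth records:  {len(ds.truth.curves)}")


if __name__ == "__main__":
    main()
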