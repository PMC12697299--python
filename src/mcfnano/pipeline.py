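"""End-to-end orchestration: simulate -> preprocess -> measure -> stats.

``run_experiment`` drives the whole chain for a set of experimental
groups under one master seed and assembles a report mirroring the study's
result tables: per-group D-spacing and modulus summaries, orientation
histograms, 0N-vs-4N Kolmogorov-Smirnov tests, Holm-Sidak-adjusted
pairwise comparisons and parameter-recovery deltas against the synthetic
ground truth.  Seeds are split per (group, mouse, site, stream) so every
unit is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .groups import GROUP_LABELS, GroupParams, default_group_params
from .indentation import FitConfig, ProbeParams, fit_hertz_cone
from .morphometry import (
    SegmentConfig,
    dspacing_from_profile,
    fibril_orientation,
    normalize_orientations,
    profile_along_trace,
    segment_fibrils,
    select_random_fibrils,
    trace_axis,
)
from .preprocess import flatten_lines
from .stats import (
    fold_change,
    holm_sidak,
    ks_two_sample,
    orientation_histogram,
    percent_difference,
    summarize,
    welch_t_pvalue,
)
from .synthgen import (
    CurveSpec,
    FibrilSpec,
    ImageSpec,
    render_fibril_image,
    seed_for,
    simulate_force_curve,
    truncated_normal,
)

logger = logging.getLogger("mcfnano")

__all__ = [
    "RunConfig",
    "RunReport",
    "run_experiment",
    "analyze_amplitude_image",
    "measure_group_images",
    "measure_group_curves",
    "recover_group_dspacing",
    "recover_group_modulus",
    "canonical_dband_check",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic experiment."""

    groups: tuple[GroupParams, ...] = tuple(
        default_group_params(label) for label in GROUP_LABELS
    )
    image_spec: ImageSpec = ImageSpec()
    curve_spec: CurveSpec = CurveSpec()
    probe: ProbeParams = ProbeParams()
    segment_config: SegmentConfig = SegmentConfig()
    fit_config: FitConfig = FitConfig()
    half_width_nm: float = 10.0
    min_separation_nm: float = 40.0
    seed: int = 0

    @staticmethod
    def from_dict(cfg: dict) -> "RunConfig":
        """Build a config from a parsed YAML/JSON mapping."""
        kwargs: dict = {}
        if "groups" in cfg:
            groups = []
            for entry in cfg["groups"]:
                if isinstance(entry, str):
                    groups.append(
                        default_group_params(entry, **cfg.get("group_overrides", {}))
                    )
                else:
                    label = entry.pop("label")
                    groups.append(default_group_params(label, **entry))
            kwargs["groups"] = tuple(groups)
        if "image" in cfg:
            kwargs["image_spec"] = ImageSpec(**cfg["image"])
        if "curve" in cfg:
            kwargs["curve_spec"] = CurveSpec(**cfg["curve"])
        if "probe" in cfg:
            kwargs["probe"] = ProbeParams(**cfg["probe"])
        if "segmentation" in cfg:
            kwargs["segment_config"] = SegmentConfig(**cfg["segmentation"])
        if "fit" in cfg:
            kwargs["fit_config"] = FitConfig(**cfg["fit"])
        for key in ("half_width_nm", "min_separation_nm", "seed"):
            if key in cfg:
                kwargs[key] = cfg[key]
        return RunConfig(**kwargs)


def analyze_amplitude_image(
    amplitude,
    params: GroupParams,
    config: RunConfig,
    orientation_seed,
):
    """Measure one raw amplitude image: flatten, segment, trace, profile.

    Returns (dspacing rows, orientation rows, traces dict).  D-spacing is
    measured on the longest traced fibrils (up to the per-site count);
    orientation on a random sample of the traced fibrils.
    """
    flat = flatten_lines(amplitude)
    labels, ids = segment_fibrils(flat, config.segment_config)
    traces = {}
    for fid in ids:
        trace = trace_axis(
            labels, fid, amplitude.pixel_size_nm, image_id=amplitude.image_id
        )
        if trace is not None:
            traces[fid] = trace

    d_rows = []
    by_length = sorted(
        traces.values(), key=lambda t: t.length_nm, reverse=True
    )
    for trace in by_length:
        if len(d_rows) >= params.fibrils_dspacing_per_site:
            break
        s, v = profile_along_trace(flat, trace, config.half_width_nm)
        meas = dspacing_from_profile(
            s, v, fibril_id=trace.fibril_id,
            min_separation_nm=config.min_separation_nm,
        )
        if meas is None:
            logger.info(
                "%s: fibril %d rejected (insufficient peaks)",
                amplitude.image_id, trace.fibril_id,
            )
            continue
        d_rows.append(
            {
                "image_id": amplitude.image_id,
                "fibril_id": trace.fibril_id,
                "d_spacing_nm": meas.d_spacing_nm,
                "n_peaks": meas.n_peaks,
                "trace_length_nm": trace.length_nm,
            }
        )

    o_rows = []
    if traces:
        chosen = select_random_fibrils(
            list(traces), n=params.fibrils_orientation_per_site,
            seed=orientation_seed,
        )
        raws = []
        for fid in chosen:
            try:
                raws.append(fibril_orientation(traces[fid]))
            except ValueError:
                continue
        if raws:
            norm = normalize_orientations([m.angle_raw_deg for m in raws])
            for meas, dev in zip(raws, norm):
                o_rows.append(
                    {
                        "image_id": amplitude.image_id,
                        "fibril_id": meas.fibril_id,
                        "angle_raw_deg": meas.angle_raw_deg,
                        "angle_norm_deg": float(dev),
                    }
                )
    return d_rows, o_rows, traces


def _match_truth(traces: dict, truth_fibrils: pd.DataFrame, px: float) -> dict:
    """Match traced fibrils to truth records by centroid-to-segment distance."""
    out = {}
    if truth_fibrils.empty:
        return out
    p0 = truth_fibrils[["x0_nm", "y0_nm"]].to_numpy()
    p1 = truth_fibrils[["x1_nm", "y1_nm"]].to_numpy()
    seg = p1 - p0
    seg_len2 = (seg**2).sum(axis=1)
    for fid, trace in traces.items():
        centroid = trace.points.mean(axis=0)  # (row, col)
        c = np.array([centroid[1] * px, centroid[0] * px])  # (x, y) nm
        t = np.clip(((c - p0) * seg).sum(axis=1) / np.maximum(seg_len2, 1e-9),
                    0, 1)
        proj = p0 + t[:, None] * seg
        dist = np.linalg.norm(proj - c, axis=1)
        out[fid] = int(truth_fibrils.index[np.argmin(dist)])
    return out


def measure_group_images(
    params: GroupParams,
    config: RunConfig,
    group_index: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate and measure every image of one group.

    Returns (dspacing, orientation, fibril truth) tables; D-spacing rows
    carry the matched true period so recovery can be audited per fibril.
    """
    d_all, o_all, truth_all = [], [], []
    for mouse in range(params.n_mice):
        for site in range(params.sites_per_mouse):
            image_id = f"{params.label}_m{mouse}_s{site}"
            amp, _hgt, truth = render_fibril_image(
                params, config.image_spec,
                seed_for(config.seed, group_index, mouse, site, 0),
                image_id=image_id,
            )
            d_rows, o_rows, traces = analyze_amplitude_image(
                amp, params, config,
                seed_for(config.seed, group_index, mouse, site, 3),
            )
            match = _match_truth(
                traces, truth.fibrils, amp.pixel_size_nm
            )
            for row in d_rows:
                idx = match.get(row["fibril_id"])
                row.update(
                    group=params.label, mouse=mouse, site=site,
                    d_true_nm=(
                        float(truth.fibrils.loc[idx, "d_nm"])
                        if idx is not None else np.nan
                    ),
                )
            for row in o_rows:
                idx = match.get(row["fibril_id"])
                row.update(
                    group=params.label, mouse=mouse, site=site,
                    angle_true_deg=(
                        float(truth.fibrils.loc[idx, "angle_deg"])
                        if idx is not None else np.nan
                    ),
                )
            d_all.extend(d_rows)
            o_all.extend(o_rows)
            truth_all.append(truth.fibrils)
            logger.info(
                "%s: %d fibrils traced, %d D-spacing, %d orientation",
                image_id, len(traces), len(d_rows), len(o_rows),
            )
    cols_d = ["group", "mouse", "site", "image_id", "fibril_id",
              "d_spacing_nm", "n_peaks", "trace_length_nm", "d_true_nm"]
    cols_o = ["group", "mouse", "site", "image_id", "fibril_id",
              "angle_raw_deg", "angle_norm_deg", "angle_true_deg"]
    return (
        pd.DataFrame(d_all, columns=cols_d) if d_all
        else pd.DataFrame(columns=cols_d),
        pd.DataFrame(o_all, columns=cols_o) if o_all
        else pd.DataFrame(columns=cols_o),
        pd.concat(truth_all, ignore_index=True) if truth_all
        else pd.DataFrame(),
    )


def measure_group_curves(
    params: GroupParams,
    config: RunConfig,
    group_index: int,
) -> pd.DataFrame:
    """Simulate and Hertz-fit every indentation curve of one group."""
    rows = []
    for mouse in range(params.n_mice):
        for site in range(params.sites_per_mouse):
            for k in range(params.indents_per_site):
                curve_id = f"{params.label}_m{mouse}_s{site}_i{k}"
                rng_e = np.random.default_rng(
                    seed_for(config.seed, group_index, mouse, site, 1, k)
                )
                e_true = truncated_normal(
                    rng_e, params.modulus_mean, params.modulus_sd
                )
                curve, truth = simulate_force_curve(
                    e_true, config.curve_spec, config.probe,
                    seed_for(config.seed, group_index, mouse, site, 2, k),
                    curve_id=curve_id,
                )
                fit = fit_hertz_cone(curve, config.probe, config.fit_config)
                rows.append(
                    {
                        "group": params.label,
                        "mouse": mouse,
                        "site": site,
                        "curve_id": curve_id,
                        "E_GPa": fit.E_gpa,
                        "z0_nm": fit.z0_nm,
                        "residual_nN": fit.residual_nN,
                        "converged": fit.converged,
                        "E_true_GPa": truth["E_gpa"],
                        "z0_true_nm": truth["z0_nm"],
                    }
                )
    return pd.DataFrame(rows)


def recover_group_dspacing(
    label: str,
    seed: int,
    n_pixels: int = 512,
    **group_overrides,
) -> tuple[float, int, pd.DataFrame]:
    """Full-pipeline D-spacing recovery for one experimental group.

    Simulates the group's complete imaging design (n_mice x sites_per_mouse
    scans at ``n_pixels`` over the 5 um field), runs flattening, tracing and
    peak-to-peak estimation, and returns (pooled mean nm, n fibrils, table).
    """
    params = default_group_params(label, **group_overrides)
    config = RunConfig(
        groups=(params,), image_spec=ImageSpec(n_pixels=n_pixels), seed=seed
    )
    gi = GROUP_LABELS.index(label)
    dspacing, _, _ = measure_group_images(params, config, gi)
    return float(dspacing["d_spacing_nm"].mean()), len(dspacing), dspacing


def recover_group_modulus(
    label: str,
    seed: int,
    n_samples: int | None = None,
    **group_overrides,
) -> tuple[float, int, pd.DataFrame]:
    """Full-pipeline modulus recovery for one experimental group.

    Simulates every indentation of the group's design (with contact-point
    offsets, baseline drift and 5% force noise), batch-fits the conical
    Hertz model and returns (mean GPa over converged fits, n, table).
    """
    params = default_group_params(label, **group_overrides)
    curve_spec = CurveSpec() if n_samples is None else CurveSpec(
        n_samples=n_samples
    )
    config = RunConfig(groups=(params,), curve_spec=curve_spec, seed=seed)
    gi = GROUP_LABELS.index(label)
    fits = measure_group_curves(params, config, gi)
    ok = fits[fits["converged"]]
    return float(ok["E_GPa"].mean()), len(ok), fits


def canonical_dband_check(
    period_nm: float = 67.0, pixel_size_nm: float = 4.8828125
) -> float:
    """Deterministic estimator check on one noise-free rendered fibril.

    Renders a single horizontal fibril (2 um long) with the given
    modulation period, zero noise and zero background, runs the full
    trace/profile/peak chain and returns the estimated D-spacing (nm).
    """
    n_pixels = 512
    spec = ImageSpec(
        n_pixels=n_pixels,
        scan_size_nm=pixel_size_nm * n_pixels,
        noise_sd=0.0,
        bow_amplitude=0.0,
    )
    center = spec.scan_size_nm / 2
    fib = FibrilSpec(
        center_x_nm=center, center_y_nm=center, angle_deg=0.0,
        length_nm=2000.0, width_nm=200.0, d_nm=period_nm,
    )
    params = default_group_params("adult-control-0N")
    amp, _, _ = render_fibril_image(params, spec, seed=0, fibrils=[fib])
    flat = flatten_lines(amp)
    labels, ids = segment_fibrils(flat)
    if not ids:
        raise RuntimeError("rendered fibril was not segmented")
    trace = trace_axis(labels, ids[0], spec.pixel_size_nm)
    s, v = profile_along_trace(flat, trace, half_width_nm=10.0)
    meas = dspacing_from_profile(s, v)
    if meas is None:
        raise RuntimeError("periodicity estimation rejected the fibril")
    return meas.d_spacing_nm


@dataclass
class RunReport:
    """All result tables of one experiment run."""

    dspacing: pd.DataFrame
    orientation: pd.DataFrame
    moduli: pd.DataFrame
    summaries: pd.DataFrame
    ks: pd.DataFrame
    pairwise: pd.DataFrame
    orientation_hist: pd.DataFrame
    recovery: pd.DataFrame
    seed: int = 0
    incomplete_groups: list = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dspacing.to_csv(out / "dspacing.csv", index=False)
        self.orientation.to_csv(out / "orientation.csv", index=False)
        self.moduli.to_csv(out / "fits.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        self.ks.to_csv(out / "ks.csv", index=False)
        self.pairwise.to_csv(out / "pairwise.csv", index=False)
        self.orientation_hist.to_csv(out / "orientation_hist.csv", index=False)
        self.recovery.to_csv(out / "recovery.csv", index=False)
        (out / "run.json").write_text(
            json.dumps(
                {"seed": self.seed, "incomplete_groups": self.incomplete_groups},
                indent=2,
            )
        )


def _group_key(label: str) -> tuple[str, str]:
    age, history, load = label.split("-")
    return f"{age}-{history}", load


def compile_statistics(
    dspacing: pd.DataFrame,
    orientation: pd.DataFrame,
    moduli: pd.DataFrame,
    groups: tuple[GroupParams, ...],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summaries, K-S table, Holm-Sidak pairwise table, histograms, recovery."""
    summaries = []
    for params in groups:
        base, load = _group_key(params.label)
        d_vals = dspacing.loc[
            dspacing["group"] == params.label, "d_spacing_nm"
        ]
        if len(d_vals):
            s = summarize(d_vals, base, load, "d_spacing_nm")
            summaries.append(s.__dict__)
        e_vals = moduli.loc[
            (moduli["group"] == params.label) & moduli["converged"], "E_GPa"
        ]
        if len(e_vals):
            s = summarize(e_vals, base, load, "modulus_GPa")
            summaries.append(s.__dict__)
    summaries = pd.DataFrame(summaries)

    # K-S: 0N vs 4N within each age/history pair, per metric
    ks_rows = []
    bases = sorted({_group_key(p.label)[0] for p in groups})
    for base in bases:
        for metric, table, col in (
            ("d_spacing_nm", dspacing, "d_spacing_nm"),
            ("angle_norm_deg", orientation, "angle_norm_deg"),
        ):
            a = table.loc[table["group"] == f"{base}-0N", col].to_numpy()
            b = table.loc[table["group"] == f"{base}-4N", col].to_numpy()
            if a.size and b.size:
                res = ks_two_sample(a, b)
                ks_rows.append(
                    {
                        "comparison": f"{base}: 0N vs 4N",
                        "metric": metric,
                        "D": res.D,
                        "p": res.p,
                        "n1": res.n1,
                        "n2": res.n2,
                    }
                )
    ks = pd.DataFrame(ks_rows)

    # pairwise Holm-Sidak over load and age contrasts per metric
    pair_rows = []
    for metric, table, col in (
        ("d_spacing_nm", dspacing, "d_spacing_nm"),
        ("modulus_GPa", moduli[moduli["converged"]] if len(moduli) else moduli,
         "E_GPa"),
    ):
        comparisons = []
        for base in bases:
            comparisons.append((f"{base}-0N", f"{base}-4N"))
        for history in ("control", "HLU"):
            for load in ("0N", "4N"):
                comparisons.append(
                    (f"adult-{history}-{load}", f"aged-{history}-{load}")
                )
        entries = []
        for ga, gb in comparisons:
            a = table.loc[table["group"] == ga, col].to_numpy()
            b = table.loc[table["group"] == gb, col].to_numpy()
            if a.size >= 2 and b.size >= 2:
                entries.append((ga, gb, a, b, welch_t_pvalue(a, b)))
        if entries:
            adj = holm_sidak([e[4] for e in entries])
            for (ga, gb, a, b, p_raw), p_adj in zip(entries, adj):
                pair_rows.append(
                    {
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "p_raw": p_raw,
                        "p_holm_sidak": float(p_adj),
                        "significant": bool(p_adj <= 0.05),
                    }
                )
    pairwise = pd.DataFrame(pair_rows)

    hist_rows = []
    for params in groups:
        sel = orientation.loc[
            orientation["group"] == params.label, "angle_norm_deg"
        ]
        if len(sel):
            h = orientation_histogram(sel)
            h.insert(0, "group", params.label)
            hist_rows.append(h)
    hist = (
        pd.concat(hist_rows, ignore_index=True) if hist_rows else pd.DataFrame()
    )

    rec_rows = []
    for params in groups:
        d_vals = dspacing.loc[dspacing["group"] == params.label,
                              "d_spacing_nm"]
        e_vals = moduli.loc[
            (moduli["group"] == params.label) & moduli["converged"], "E_GPa"
        ] if len(moduli) else pd.Series(dtype=float)
        e_truth = moduli.loc[moduli["group"] == params.label, "E_true_GPa"] \
            if "E_true_GPa" in moduli.columns else pd.Series(dtype=float)
        d_truth = dspacing.loc[dspacing["group"] == params.label, "d_true_nm"] \
            if "d_true_nm" in dspacing.columns else pd.Series(dtype=float)
        rec_rows.append(
            {
                "group": params.label,
                "d_generative_nm": params.d_mean,
                "d_truth_sample_nm": float(d_truth.mean())
                if len(d_truth) else np.nan,
                "d_recovered_nm": float(d_vals.mean())
                if len(d_vals) else np.nan,
                "d_delta_nm": float(d_vals.mean() - params.d_mean)
                if len(d_vals) else np.nan,
                "n_fibrils": int(len(d_vals)),
                "E_generative_GPa": params.modulus_mean,
                "E_truth_sample_GPa": float(e_truth.mean())
                if len(e_truth) else np.nan,
                "E_recovered_GPa": float(e_vals.mean())
                if len(e_vals) else np.nan,
                "E_delta_GPa": float(e_vals.mean() - params.modulus_mean)
                if len(e_vals) else np.nan,
                "n_curves": int(len(e_vals)),
            }
        )
    recovery = pd.DataFrame(rec_rows)
    return summaries, ks, pairwise, hist, recovery


def run_experiment(config: RunConfig, outdir=None) -> RunReport:
    """Execute all stages for every group; failures flag the group only."""
    d_tables, o_tables, m_tables = [], [], []
    incomplete = []
    for gi, params in enumerate(config.groups):
        try:
            d, o, _truth = measure_group_images(params, config, gi)
            d_tables.append(d)
            o_tables.append(o)
        except Exception:
            logger.exception("image stage failed for %s", params.label)
            incomplete.append(params.label)
        try:
            m_tables.append(measure_group_curves(params, config, gi))
        except Exception:
            logger.exception("curve stage failed for %s", params.label)
            if params.label not in incomplete:
                incomplete.append(params.label)

    dspacing = pd.concat(d_tables, ignore_index=True) if d_tables \
        else pd.DataFrame(columns=["group", "d_spacing_nm"])
    orientation = pd.concat(o_tables, ignore_index=True) if o_tables \
        else pd.DataFrame(columns=["group", "angle_norm_deg"])
    moduli = pd.concat(m_tables, ignore_index=True) if m_tables \
        else pd.DataFrame(columns=["group", "E_GPa", "converged"])
    summaries, ks, pairwise, hist, recovery = compile_statistics(
        dspacing, orientation, moduli, config.groups
    )
    report = RunReport(
        dspacing=dspacing,
        orientation=orientation,
        moduli=moduli,
        summaries=summaries,
        ks=ks,
        pairwise=pairwise,
        orientation_hist=hist,
        recovery=recovery,
        seed=config.seed,
        incomplete_groups=incomplete,
    )
    if outdir is not None:
        report.write(outdir)
    return report
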