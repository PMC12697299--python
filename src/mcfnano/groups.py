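"""Experimental group definitions and their generative parameters.

The study design crosses two ages (adult, aged) with two mechanical
histories (control, hindlimb-unloading/HLU) and images each tibia under two
axial loads (0 N, 4 N), giving eight groups of n = 6 mice.  Each group
carries the published D-periodic-spacing and radial-modulus statistics,
which the synthetic generator uses as ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

GROUP_LABELS: tuple[str, ...] = (
    "adult-control-0N",
    "adult-control-4N",
    "adult-HLU-0N",
    "adult-HLU-4N",
    "aged-control-0N",
    "aged-control-4N",
    "aged-HLU-0N",
    "aged-HLU-4N",
)

# (d_mean nm, d_sd nm, modulus_mean GPa, modulus_sd GPa) per group,
# reported group mean ± SD of the murine tibia measurements.
_GROUP_TABLE: dict[str, tuple[float, float, float, float]] = {
    "adult-control-0N": (70.0, 9.0, 0.30, 0.13),
    "adult-control-4N": (70.0, 9.0, 0.39, 0.13),
    "adult-HLU-0N": (71.0, 13.0, 0.32, 0.11),
    "adult-HLU-4N": (76.0, 7.0, 0.33, 0.09),
    "aged-control-0N": (77.0, 11.0, 0.74, 0.17),
    "aged-control-4N": (76.0, 12.0, 0.67, 0.15),
    "aged-HLU-0N": (74.0, 11.0, 0.77, 0.23),
    "aged-HLU-4N": (77.0, 11.0, 0.75, 0.29),
}


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one experimental group.

    Attributes
    ----------
    label:
        One of :data:`GROUP_LABELS` (``<age>-<history>-<load>``).
    d_mean, d_sd:
        Mean and across-fibril dispersion of the true D-period, nm.
    angle_sd:
        Dispersion of fibril axis angles about the dominant direction of
        the image, degrees.
    modulus_mean, modulus_sd:
        Mean and across-site dispersion of the true radial elastic
        modulus, GPa.
    n_mice, sites_per_mouse:
        Animals per group and scan sites per tibia (sites spaced ~1 mm
        along the anterior-medial surface).
    fibrils_dspacing_per_site:
        Fibrils whose D-period is measured per site (the longest traces).
    fibrils_orientation_per_site:
        Fibrils randomly sampled per image for orientation analysis.
    indents_per_site:
        Nanoindentation curves recorded per site.
    """

    label: str
    d_mean: float
    d_sd: float
    modulus_mean: float
    modulus_sd: float
    angle_sd: float = 15.0
    n_mice: int = 6
    sites_per_mouse: int = 5
    fibrils_dspacing_per_site: int = 10
    fibrils_orientation_per_site: int = 20
    indents_per_site: int = 20

    def __post_init__(self) -> None:
        if self.d_mean <= 0:
            raise ValueError(f"d_mean must be > 0, got {self.d_mean}")
        if self.d_sd < 0:
            raise ValueError(f"d_sd must be >= 0, got {self.d_sd}")
        if self.modulus_mean <= 0:
            raise ValueError(
                f"modulus_mean must be > 0, got {self.modulus_mean}"
            )
        if self.modulus_sd < 0:
            raise ValueError(f"modulus_sd must be >= 0, got {self.modulus_sd}")
        if self.angle_sd < 0:
            raise ValueError(f"angle_sd must be >= 0, got {self.angle_sd}")
        for name in (
            "n_mice",
            "sites_per_mouse",
            "fibrils_dspacing_per_site",
            "fibrils_orientation_per_site",
            "indents_per_site",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def age(self) -> str:
        return self.label.split("-")[0]

    @property
    def history(self) -> str:
        return self.label.split("-")[1]

    @property
    def load(self) -> str:
        return self.label.split("-")[2]


def default_group_params(label: str, **overrides) -> GroupParams:
    """Return the published group statistics as generative defaults.

    Parameters
    ----------
    label:
        Group name, e.g. ``"adult-control-0N"``.
    **overrides:
        Replace any :class:`GroupParams` field (e.g. ``n_mice=2`` for a
        scaled-down simulation).

    Raises
    ------
    ValueError
        If ``label`` is not one of the eight defined groups.
    """
    if label not in _GROUP_TABLE:
        raise ValueError(
            f"unknown group label {label!r}; expected one of {GROUP_LABELS}"
        )
    d_mean, d_sd, e_mean, e_sd = _GROUP_TABLE[label]
    params = GroupParams(
        label=label,
        d_mean=d_mean,
        d_sd=d_sd,
        modulus_mean=e_mean,
        modulus_sd=e_sd,
    )
    if overrides:
        params = replace(params, **overrides)
    return params
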