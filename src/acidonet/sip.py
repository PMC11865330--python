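"""DNA-SIP density-fraction analysis.

Taxa assimilating a 13C-labelled substrate build heavier DNA, so their marker
gene distribution over CsCl buoyant-density fractions shifts toward the dense
end relative to a 12C control.  This module normalizes fraction profiles,
computes weighted mean densities (WMD), detects label shifts, and summarizes
the guild composition of the "heavy" density window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SipProfile:
    """One qPCR profile over ordered buoyant-density fractions."""

    density: np.ndarray   # g/mL, strictly monotone increasing
    copies: np.ndarray    # marker copies per fraction, >= 0
    treatment: str = "13C"
    guild: str = ""
    condition: str = ""
    replicate: int = 1

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.copies = np.asarray(self.copies, dtype=float)
        if self.density.shape != self.copies.shape or self.density.ndim != 1:
            raise ValueError("density and copies must be 1-D of equal length")
        if len(self.density) < 10:
            raise ValueError("need >= 10 fractions")
        if not (np.diff(self.density) > 0).all():
            raise ValueError("densities must be strictly increasing")
        if (self.copies < 0).any():
            raise ValueError("copies must be >= 0")

    @property
    def total(self) -> float:
        return float(self.copies.sum())


def profiles_from_tidy(df: pd.DataFrame) -> dict:
    """Group a tidy SIP table into ``{(treatment, guild, replicate): SipProfile}``.

    Expects the columns written by the synthetic generator: treatment,
    replicate, guild, fraction_index, density_g_per_mL, copies.  Replicates
    are averaged out by passing the result through :func:`mean_profile`.
    """
    out = {}
    for (tr, guild, rep), grp in df.groupby(["treatment", "guild", "replicate"]):
        grp = grp.sort_values("density_g_per_mL")
        out[(tr, guild, int(rep))] = SipProfile(
            grp["density_g_per_mL"].to_numpy(),
            grp["copies"].to_numpy(),
            treatment=tr, guild=guild, replicate=int(rep),
        )
    return out


def mean_profile(profiles) -> SipProfile:
    """Average copies over replicate profiles sharing one density grid."""
    profiles = list(profiles)
    base = profiles[0]
    for p in profiles[1:]:
        if not np.allclose(p.density, base.density):
            raise ValueError("replicate profiles must share the density grid")
    copies = np.mean([p.copies for p in profiles], axis=0)
    return SipProfile(base.density, copies, treatment=base.treatment,
                      guild=base.guild, condition=base.condition)


def normalize_profile(profile: SipProfile):
    """Per-fraction share of copies (sums to 1) plus the profile total.

    The total supports the labelled-vs-control total check: a label shift
    should redistribute copies across fractions, not change their sum.
    """
    total = profile.total
    if total <= 0:
        raise ValueError("degenerate all-zero profile")
    return profile.copies / total, total


def weighted_mean_density(profile: SipProfile) -> float:
    """Copies-weighted mean buoyant density (g/mL) of the profile."""
    shares, _ = normalize_profile(profile)
    return float((shares * profile.density).sum())


def detect_label_shift(
    labeled: SipProfile,
    control: SipProfile,
    min_shift: float = 0.005,
) -> dict:
    """WMD(labeled) - WMD(control) and whether it clears ``min_shift`` g/mL.

    Profiles on different grids are compared after linear interpolation of
    the control onto the labelled grid; grids that do not overlap raise.
    """
    if labeled.density.shape == control.density.shape and np.allclose(
        labeled.density, control.density
    ):
        ctrl = control
    else:
        lo = max(labeled.density[0], control.density[0])
        hi = min(labeled.density[-1], control.density[-1])
        if hi <= lo:
            raise ValueError("density grids do not overlap; cannot compare")
        grid = labeled.density[(labeled.density >= lo) & (labeled.density <= hi)]
        if len(grid) < 10:
            raise ValueError("grid overlap too short after interpolation")
        lab_copies = np.interp(grid, labeled.density, labeled.copies)
        ctl_copies = np.interp(grid, control.density, control.copies)
        labeled = SipProfile(grid, lab_copies, treatment=labeled.treatment,
                             guild=labeled.guild)
        ctrl = SipProfile(grid, ctl_copies, treatment=control.treatment,
                          guild=control.guild)
    shift = weighted_mean_density(labeled) - weighted_mean_density(ctrl)
    return {"shift": shift, "is_labeled": bool(shift >= min_shift)}


def heavy_fraction_composition(
    profiles: dict,
    heavy_window: tuple = (1.72, 1.75),
) -> pd.Series:
    """Guild shares of total copies inside the heavy density window.

    ``profiles`` maps guild -> SipProfile (same grid; differing grids are
    linearly interpolated onto the first profile's grid).  Shares are
    normalized to sum to 1 across guilds.
    """
    lo, hi = heavy_window
    if hi <= lo:
        raise ValueError("heavy window must be a non-empty density interval")
    items = list(profiles.items())
    base = items[0][1].density
    mass = {}
    for guild, prof in items:
        if prof.density.shape == base.shape and np.allclose(prof.density, base):
            dens, cop = prof.density, prof.copies
        else:
            dens = base
            cop = np.interp(base, prof.density, prof.copies)
        sel = (dens >= lo) & (dens <= hi)
        if not sel.any():
            raise ValueError("heavy window lies outside the density grid")
        mass[guild] = float(cop[sel].sum())
    total = sum(mass.values())
    if total <= 0:
        raise ValueError("no copies in the heavy window for any guild")
    return pd.Series({g: m / total for g, m in mass.items()}, name="heavy_share")
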