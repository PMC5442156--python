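"""Plate normalization and hit calling for the RNAi screen.

Primary screen: each well's MitosisCount is converted to a robust z-score
against the plate's *sample* wells (controls excluded from the reference
statistics), with the sign oriented so that a *reduced* MitosisCount gives
a *positive* z — positive viability controls must come out at z >= 2.  A
target is a bioinformatic hit when at least two of its siRNAs reach z >= 2,
and a manual hit when at least three siRNAs score >= 3 or at least two
score >= 4 on the ordinal 1-5 phenotype scale.

Validation screen: hits are re-arrayed on fresh plates, so the plate median
no longer reflects a null population and z-scores are not meaningful;
instead each well's raw MitosisCount is divided by the median of the
plate's negative-control wells (raw/mnc).  A hit validates when the same
two or more siRNAs that had an effect in the primary screen show
raw/mnc <= 0.8 or a manual score >= 3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import CONTROL_LABELS, NEGATIVE_CONTROLS, EMPTY, is_sample

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: 1/Phi^-1(3/4), MAD -> sigma for normal data


class ZeroSpreadError(ValueError):
    """Raised when the sample MAD is zero and no fallback is allowed."""


def robust_z(
    sample_values: Sequence[float] | np.ndarray,
    x: float | np.ndarray,
    *,
    fallback_sd: bool = False,
) -> float | np.ndarray:
    """Robust z-score of ``x`` against the sample-well distribution.

    z = (median(sample) - x) / (1.4826 * MAD(sample)).  The inverted
    numerator makes wells with *fewer* mitoses score *higher*.  Location/
    scale equivariant: z(a*s+b, a*x+b) = z(s, x) for a > 0.  If the MAD is
    zero, raises :class:`ZeroSpreadError` unless ``fallback_sd`` is set, in
    which case the standard deviation replaces 1.4826*MAD (logged).
    """
    s = np.asarray(sample_values, dtype=float)
    if s.size < 8:
        raise ValueError(f"need >= 8 sample values for a stable reference, got {s.size}")
    med = np.median(s)
    mad = np.median(np.abs(s - med))
    scale = MAD_SCALE * mad
    if scale == 0:
        if not fallback_sd:
            raise ZeroSpreadError("sample MAD is zero")
        scale = s.std(ddof=1)
        log.warning("sample MAD is zero; falling back to SD = %.4g", scale)
        if scale == 0:
            raise ZeroSpreadError("sample values are constant")
    return (med - np.asarray(x, dtype=float)) / scale


def raw_over_mnc(x: float | np.ndarray, nc_values: Sequence[float]) -> float | np.ndarray:
    """Raw MitosisCount divided by the median of the negative controls."""
    nc = np.asarray(nc_values, dtype=float)
    if nc.size == 0:
        raise ValueError("no negative-control values")
    med = np.median(nc)
    if med <= 0:
        raise ValueError("negative-control median must be positive")
    return np.asarray(x, dtype=float) / med


def score_plates(
    wells: pd.DataFrame,
    value_col: str = "mitosis_count",
    *,
    fallback_sd: bool = False,
) -> pd.DataFrame:
    """Add a robust ``z`` column per plate, referenced to that plate's
    sample wells.  ``wells`` needs columns plate, content and ``value_col``."""
    out = []
    for plate, grp in wells.groupby("plate", sort=True):
        sample = grp.loc[grp["content"].map(is_sample), value_col]
        z = robust_z(sample.to_numpy(), grp[value_col].to_numpy(), fallback_sd=fallback_sd)
        out.append(grp.assign(z=z))
    return pd.concat(out, ignore_index=True) if out else wells.assign(z=np.nan)


def validation_normalize(
    wells: pd.DataFrame,
    value_col: str = "mitosis_count",
) -> pd.DataFrame:
    """Add a ``raw_mnc`` column per plate (negative-control median division)."""
    neg = set(NEGATIVE_CONTROLS) | {EMPTY}
    out = []
    for plate, grp in wells.groupby("plate", sort=True):
        nc = grp.loc[grp["content"].isin(neg), value_col]
        out.append(grp.assign(raw_mnc=raw_over_mnc(grp[value_col].to_numpy(), nc.to_numpy())))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# hit calling


@dataclass(frozen=True)
class ScreenSummary:
    """Hit bookkeeping for the primary + validation screens."""

    n_bioinformatic: int
    n_manual: int
    n_overlap: int
    n_union: int
    n_validated: int
    n_validated_both: int

    def __post_init__(self) -> None:
        if self.n_union != self.n_bioinformatic + self.n_manual - self.n_overlap:
            raise ValueError("union must equal bioinformatic + manual - overlap")
        if self.n_overlap > min(self.n_bioinformatic, self.n_manual):
            raise ValueError("overlap cannot exceed either hit set")


def call_primary(
    sirna_table: pd.DataFrame,
    z_cut: float = 2.0,
    manual_cut_weak: int = 3,
    n_weak: int = 3,
    manual_cut_strong: int = 4,
    n_strong: int = 2,
    n_z: int = 2,
) -> pd.DataFrame:
    """Primary-screen hit calls per target.

    ``sirna_table`` needs columns target, sirna, z, manual_score.  Returns
    one row per target with ``bioinformatic_hit`` (>= ``n_z`` siRNAs at
    z >= ``z_cut``), ``manual_hit`` (>= 3 siRNAs scoring >= 3, or >= 2
    scoring >= 4) and ``hit`` (either).  Also adds a per-siRNA
    ``primary_effect`` column to the input view: the siRNA counted toward
    either rule (z >= z_cut or manual score >= 3), which the validation
    screen's "same siRNAs" requirement consumes.
    """
    scores = sirna_table["manual_score"]
    if not scores.isin([1, 2, 3, 4, 5]).all():
        raise ValueError("manual scores must be integers in 1..5")
    df = sirna_table.copy()
    df["z_effect"] = df["z"] >= z_cut
    df["primary_effect"] = df["z_effect"] | (df["manual_score"] >= manual_cut_weak)
    g = df.groupby("target", sort=True)
    counts = pd.DataFrame({
        "n_z": g["z_effect"].sum(),
        "n_weak": (df["manual_score"] >= manual_cut_weak).groupby(df["target"]).sum(),
        "n_strong": (df["manual_score"] >= manual_cut_strong).groupby(df["target"]).sum(),
    })
    calls = pd.DataFrame({
        "target": counts.index,
        "bioinformatic_hit": (counts["n_z"] >= n_z).to_numpy(),
        "manual_hit": ((counts["n_weak"] >= n_weak)
                       | (counts["n_strong"] >= n_strong)).to_numpy(),
    }).reset_index(drop=True)
    calls["hit"] = calls["bioinformatic_hit"] | calls["manual_hit"]
    calls.attrs["sirna_effects"] = df
    return calls


def call_validation(
    primary_sirnas: pd.DataFrame,
    validation: pd.DataFrame,
    mnc_cut: float = 0.8,
    manual_cut: int = 3,
    n_required: int = 2,
) -> pd.DataFrame:
    """Validation calls: target validated iff >= ``n_required`` siRNAs that
    had a primary effect show raw/mnc <= ``mnc_cut`` or a validation manual
    score >= ``manual_cut``.

    ``primary_sirnas`` needs columns target, sirna, primary_effect;
    ``validation`` needs sirna, raw_mnc, manual_score.  A primary-effect
    siRNA missing from the validation table is an error.  Returns one row
    per target with validated / validated_mnc / validated_manual flags
    (the latter two: the rule met through that criterion alone).
    """
    val = validation.set_index("sirna")
    flagged = primary_sirnas[primary_sirnas["primary_effect"]]
    missing = set(flagged["sirna"]) - set(val.index)
    if missing:
        raise ValueError(f"validation records missing for primary-effect siRNAs: {sorted(missing)[:5]}")
    rows = []
    for target, grp in primary_sirnas.groupby("target", sort=True):
        eff = grp[grp["primary_effect"]]
        v = val.loc[eff["sirna"]]
        ok_mnc = v["raw_mnc"] <= mnc_cut
        ok_manual = v["manual_score"] >= manual_cut
        n_ok = int((ok_mnc | ok_manual).sum())
        rows.append({
            "target": target,
            "validated": n_ok >= n_required,
            "validated_mnc": int(ok_mnc.sum()) >= n_required,
            "validated_manual": int(ok_manual.sum()) >= n_required,
        })
    return pd.DataFrame(rows)


def summarize(
    primary_calls: pd.DataFrame,
    validation_calls: pd.DataFrame | None = None,
) -> ScreenSummary:
    """Venn-style hit counts across the bioinformatic and manual analyses."""
    bio = set(primary_calls.loc[primary_calls["bioinformatic_hit"], "target"])
    man = set(primary_calls.loc[primary_calls["manual_hit"], "target"])
    n_validated = n_both = 0
    if validation_calls is not None:
        n_validated = int(validation_calls["validated"].sum())
        if {"validated_mnc", "validated_manual"} <= set(validation_calls.columns):
            n_both = int((validation_calls["validated_mnc"]
                          & validation_calls["validated_manual"]).sum())
    return ScreenSummary(
        n_bioinformatic=len(bio),
        n_manual=len(man),
        n_overlap=len(bio & man),
        n_union=len(bio | man),
        n_validated=n_validated,
        n_validated_both=n_both,
    )
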