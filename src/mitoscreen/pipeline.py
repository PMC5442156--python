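"""End-to-end screen driver.

Two execution paths share one generative model:

* the *fast* path simulates per-well MitosisCounts directly from the
  aggregate branching model (seconds for a whole screen), and
* the *full* path renders each well's movie, segments the nuclei, links
  tracks and counts splits — exercised on small movies since it is orders
  of magnitude slower.

``run_screen`` performs: simulate -> score (robust z per plate) -> call
hits -> validation screen (raw/mnc on re-arrayed hit siRNAs) -> summary,
and writes all tables plus a run manifest (seed + config hash).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cell_tracking import mitosis_count, track_movie
from .config import PipelineConfig
from .io import write_table
from .screen_scoring import (
    call_primary,
    call_validation,
    score_plates,
    summarize,
    validation_normalize,
)
from .synthetic_data import (
    CellEventLog,
    LibraryDesign,
    MovieSpec,
    NULL_PHENOTYPE,
    PlateLayout,
    WellPhenotype,
    _rng,
    control_phenotypes,
    is_sample,
    make_library,
    make_plates,
    render_movie,
    simulate_well,
    simulate_well_counts,
    synthesize_manual_scores,
)


def movie_spec_from(cfg: PipelineConfig) -> MovieSpec:
    return MovieSpec(
        frame_px=cfg.frame_px, pixel_um=cfg.pixel_um, interval_h=cfg.interval_h,
        t_start=cfg.t_start, t_end=cfg.t_end, nucleus_radius_um=cfg.nucleus_radius_um,
        psf_sigma_px=cfg.psf_sigma_px, background=cfg.background,
        noise_sd=cfg.noise_sd, brownian_sd_um=cfg.brownian_sd_um,
    )


def mitosis_count_fast(log: CellEventLog) -> int:
    """Fast-path MitosisCount of a well: divisions straight off the event log."""
    return log.n_divisions


def assign_true_phenotypes(
    library: LibraryDesign,
    cfg: PipelineConfig,
    seed: int,
) -> dict[str, WellPhenotype]:
    """Latent ground-truth phenotype per siRNA.

    A ``hit_fraction`` of targets carries a true phenotype (viability or
    mitotic arrest, equal odds) with a per-target effect drawn uniformly;
    each individual siRNA then either fails outright (``sirna_failure_rate``)
    or delivers the target effect attenuated by its own efficacy.
    """
    rng = _rng(seed, 11)
    pheno: dict[str, WellPhenotype] = {}
    for target in library.targets:
        if rng.random() < cfg.hit_fraction:
            effect = rng.uniform(cfg.hit_effect_min, cfg.hit_effect_max)
            klass = "viability" if rng.random() < 0.5 else "mitotic_arrest"
        else:
            effect, klass = 0.0, "none"
        for sirna in library.sirnas[target]:
            if effect > 0 and rng.random() >= cfg.sirna_failure_rate:
                efficacy = rng.uniform(0.6, 1.0)
                pheno[sirna] = WellPhenotype(effect * efficacy, klass, cfg.delay_h)
            else:
                pheno[sirna] = NULL_PHENOTYPE
    return pheno


def simulate_wells(
    plates: list[PlateLayout],
    phenotypes: Mapping[str, WellPhenotype],
    cfg: PipelineConfig,
    seed: int,
) -> pd.DataFrame:
    """Fast-path MitosisCount for every well of every plate.

    ``phenotypes`` maps well content (control label or siRNA id) to a
    phenotype; unmapped contents behave as null.
    """
    frames = []
    for pi, plate in enumerate(plates):
        wells = sorted(plate.wells.items())
        phen = [phenotypes.get(content, NULL_PHENOTYPE) for _, content in wells]
        counts = simulate_well_counts(
            phen, n_cells=cfg.n_cells, baseline_division_rate=cfg.division_rate,
            t_start=cfg.t_start, t_end=cfg.t_end, dt=cfg.interval_h,
            interphase_death_rate=cfg.interphase_death_rate, rate_cv=cfg.rate_cv,
            rng=_rng(seed, 22, pi),
        )
        frames.append(pd.DataFrame({
            "plate": plate.plate,
            "well": [w for w, _ in wells],
            "content": [c for _, c in wells],
            "mitosis_count": counts,
        }))
    return pd.concat(frames, ignore_index=True)


def run_well_full(
    phenotype: WellPhenotype,
    cfg: PipelineConfig,
    seed: int,
    n_cells: int | None = None,
) -> tuple[int, CellEventLog]:
    """Full imaging path for one well: simulate, render, segment, track.

    Returns (MitosisCount from detected track splits, ground-truth log).
    """
    spec = movie_spec_from(cfg)
    log = simulate_well(
        phenotype, n_cells=cfg.n_cells if n_cells is None else n_cells,
        baseline_division_rate=cfg.division_rate, spec=spec, seed=seed,
        interphase_death_rate=cfg.interphase_death_rate,
        normal_mitosis_h=cfg.normal_mitosis_h,
        arrest_max_h=cfg.arrest_max_h,
    )
    stacks = render_movie(log, spec, seed=seed)
    radius_px = cfg.nucleus_radius_um / cfg.pixel_um
    _, events = track_movie(
        stacks["H2B_red"],
        max_dist=radius_px, split_radius=2.0 * radius_px, split_window=2,
    )
    return mitosis_count(events), log


def manual_scores_for(
    wells: pd.DataFrame,
    phenotypes: Mapping[str, WellPhenotype],
    cfg: PipelineConfig,
    seed: int,
) -> np.ndarray:
    """Ordinal 1-5 scores per well from the latent phenotype severity."""
    effects = [phenotypes.get(c, NULL_PHENOTYPE).effect for c in wells["content"]]
    return synthesize_manual_scores(effects, noise_sd=cfg.manual_noise_sd, seed=seed)


def run_screen(
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate and analyse a whole screen; returns the result bundle.

    Bundle keys: library, plates, wells (with z), sirna_table,
    primary_calls, validation_wells, validation_calls, summary, manifest.
    """
    cfg = cfg or PipelineConfig()
    library = make_library(cfg.n_targets, cfg.max_sirnas_per_target, seed=seed)
    plates = make_plates(library, cfg.plate_rows, cfg.plate_cols, seed=seed,
                         include_mitotic_controls=cfg.include_mitotic_controls)
    phenotypes: dict[str, WellPhenotype] = control_phenotypes(
        cfg.positive_effect, cfg.mitotic_ctrl_effect, cfg.delay_h)
    phenotypes.update(assign_true_phenotypes(library, cfg, seed))

    if cfg.fast:
        wells = simulate_wells(plates, phenotypes, cfg, seed)
    else:
        rows = []
        for pi, plate in enumerate(plates):
            for wi, (well, content) in enumerate(sorted(plate.wells.items())):
                count, _ = run_well_full(phenotypes.get(content, NULL_PHENOTYPE),
                                         cfg, seed=int(_rng(seed, 33, pi, wi).integers(2**31)))
                rows.append({"plate": plate.plate, "well": well, "content": content,
                             "mitosis_count": count})
        wells = pd.DataFrame(rows)

    wells = score_plates(wells)
    wells["manual_score"] = manual_scores_for(wells, phenotypes, cfg, seed)

    target_of = library.target_of()
    samples = wells[wells["content"].map(is_sample)].copy()
    sirna_table = pd.DataFrame({
        "target": samples["content"].map(target_of),
        "sirna": samples["content"],
        "z": samples["z"],
        "manual_score": samples["manual_score"],
    }).reset_index(drop=True)
    primary_calls = call_primary(sirna_table, z_cut=cfg.z_cut)
    sirna_effects = primary_calls.attrs["sirna_effects"]

    # validation screen: re-array every siRNA of every hit target
    hit_targets = list(primary_calls.loc[primary_calls["hit"], "target"])
    validation_wells = validation_calls = None
    if hit_targets:
        sub = LibraryDesign(targets=tuple(hit_targets),
                            sirnas={t: library.sirnas[t] for t in hit_targets})
        vplates = make_plates(sub, cfg.plate_rows, cfg.plate_cols, seed=seed + 1,
                              include_mitotic_controls=cfg.include_mitotic_controls)
        vwells = simulate_wells(vplates, phenotypes, cfg, seed + 1)
        vwells = validation_normalize(vwells)
        vwells["manual_score"] = manual_scores_for(vwells, phenotypes, cfg, seed + 1)
        validation_wells = vwells
        vsamples = vwells[vwells["content"].map(is_sample)]
        vtable = pd.DataFrame({
            "sirna": vsamples["content"],
            "raw_mnc": vsamples["raw_mnc"],
            "manual_score": vsamples["manual_score"],
        }).reset_index(drop=True)
        hit_sirnas = sirna_effects[sirna_effects["target"].isin(hit_targets)]
        validation_calls = call_validation(hit_sirnas, vtable,
                                           mnc_cut=cfg.mnc_cut, manual_cut=cfg.manual_cut)

    summary = summarize(primary_calls, validation_calls)
    manifest = {"seed": int(seed), "config_hash": cfg.hash(),
                "version": __version__, "n_plates": len(plates)}
    bundle = {
        "library": library, "plates": plates, "wells": wells,
        "sirna_table": sirna_effects, "primary_calls": primary_calls,
        "validation_wells": validation_wells, "validation_calls": validation_calls,
        "summary": summary, "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(wells, out / "wells.tsv", "wells")
        write_table(sirna_effects, out / "sirna_table.tsv", "sirna_table")
        write_table(primary_calls, out / "primary_calls.tsv", "primary_calls")
        if validation_wells is not None:
            write_table(validation_wells, out / "validation_wells.tsv", "validation_wells")
            write_table(validation_calls, out / "validation_calls.tsv", "validation_calls")
        write_table(pd.DataFrame([summary.__dict__]), out / "screen_summary.tsv", "screen_summary")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        cfg.save(out / "config.txt")
    return bundle


# ---------------------------------------------------------------------------
# control-performance summaries (screen quality metrics)


def _control_plates(cfg: PipelineConfig, n_plates: int, seed: int) -> list[PlateLayout]:
    """Exactly ``n_plates`` full plates: the standard control complement
    (2x3 positive, 2x3 negative, 2x3 mitotic-defect, 1 empty) and sample
    wells filling the rest, as on a production screen plate."""
    n_controls = 19 if cfg.include_mitotic_controls else 13
    capacity = cfg.plate_rows * cfg.plate_cols - n_controls
    needed = n_plates * capacity
    full, rest = divmod(needed, 5)
    targets = tuple(f"LNC{i:04d}" for i in range(full + (1 if rest else 0)))
    sirnas = {t: tuple(f"{t}_s{j + 1}" for j in range(5)) for t in targets[:full]}
    if rest:
        sirnas[targets[-1]] = tuple(f"{targets[-1]}_s{j + 1}" for j in range(rest))
    lib = LibraryDesign(targets=targets, sirnas=sirnas)
    return make_plates(lib, cfg.plate_rows, cfg.plate_cols, seed=seed,
                       include_mitotic_controls=cfg.include_mitotic_controls)


def negative_control_specificity(
    cfg: PipelineConfig | None = None,
    n_plates: int = 20,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of negative-control wells (non-targeting + empty) with z < 2
    when every well — control or sample — follows the null count law.

    Returns (fraction, number of control wells).  This is the screen's
    specificity floor: with controls drawn from the same distribution as
    the ~300 sample wells, robust z against the sample median/MAD leaves
    roughly the upper normal tail above 2.
    """
    cfg = cfg or PipelineConfig()
    plates = _control_plates(cfg, n_plates, seed)
    wells = simulate_wells(plates, {}, cfg, seed)  # all wells null
    wells = score_plates(wells)
    from .synthetic_data import EMPTY, NEGATIVE_CONTROLS

    neg = wells[wells["content"].isin(list(NEGATIVE_CONTROLS) + [EMPTY])]
    return float((neg["z"] < cfg.z_cut).mean()), int(len(neg))


def positive_control_detection(
    cfg: PipelineConfig | None = None,
    n_plates: int = 20,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of positive viability-control wells reaching z >= 2 under
    the default strong knockdown (rate multiplier 1 - positive_effect after
    the penetration delay), with null sample wells.

    Returns (fraction, number of positive-control wells).
    """
    cfg = cfg or PipelineConfig()
    plates = _control_plates(cfg, n_plates, seed)
    phen = control_phenotypes(cfg.positive_effect, cfg.mitotic_ctrl_effect, cfg.delay_h)
    wells = simulate_wells(plates, phen, cfg, seed)
    wells = score_plates(wells)
    from .synthetic_data import POSITIVE_CONTROLS

    pos = wells[wells["content"].isin(POSITIVE_CONTROLS)]
    return float((pos["z"] >= cfg.z_cut).mean()), int(len(pos))
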