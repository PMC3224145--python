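"""Convenience drivers chaining simulation, dual scans and comparison.

These helpers wire the individual modules together the way the analysis is
meant to be run: scan the same cohort once per measurement (or on a trimmed
subset, the measurement mean, or threshold-coded 0/1 status) and compare the
two scans.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import ConcordanceReport, compare_gwas
from .mixed_gwas import GwasResult, run_gwas
from .pedigree import RelationshipMatrix, build_nrm
from .synthetic_data import SimulatedStudy, SimulationConfig, calibrate_error_sd

__all__ = ["dual_gwas", "compare_measurement_gwas", "config_for_reliability"]


def dual_gwas(
    study: SimulatedStudy,
    phenotypes: Sequence[pd.Series] | None = None,
    ids: Sequence[str] | None = None,
    mode: str = "p3d",
    nrm: RelationshipMatrix | None = None,
    alphas: Sequence[float] = (0.001, 0.0001),
) -> list[GwasResult]:
    """Run one scan per phenotype vector on a (possibly trimmed) cohort.

    ``phenotypes`` defaults to the two raw measurements; ``ids`` restricts
    the cohort (e.g. after trimming).  The pedigree NRM is built once over
    the analysed animals and shared by the scans.
    """
    if phenotypes is None:
        phenotypes = [study.measurement_1.rename("m1"), study.measurement_2.rename("m2")]
    if ids is None:
        ids = list(study.cohort)
    ids = [str(a) for a in ids]
    if nrm is None:
        nrm = build_nrm(study.pedigree, order=ids)
    else:
        nrm = nrm.reorder(ids)
    dosages = study.cohort_dosages().loc[ids]
    results = []
    for y in phenotypes:
        results.append(
            run_gwas(
                y.loc[ids],
                study.factors.loc[ids],
                nrm,
                dosages,
                study.snp_map,
                mode=mode,
                trait_name=str(y.name),
                alphas=alphas,
            )
        )
    return results


def compare_measurement_gwas(
    study: SimulatedStudy,
    ids: Sequence[str] | None = None,
    mode: str = "p3d",
    alphas: Sequence[float] = (0.001, 0.0001),
    nrm: RelationshipMatrix | None = None,
) -> tuple[ConcordanceReport, list[GwasResult]]:
    """Dual scan of the two measurements plus the full concordance report."""
    results = dual_gwas(study, ids=ids, mode=mode, nrm=nrm, alphas=alphas)
    ids = [str(a) for a in (ids if ids is not None else study.cohort)]
    report = compare_gwas(
        results[0],
        results[1],
        alphas=alphas,
        y1=study.measurement_1.loc[ids],
        y2=study.measurement_2.loc[ids],
    )
    return report, results


def config_for_reliability(
    base: SimulationConfig, reliability: float, seed: int | None = None
) -> SimulationConfig:
    """Config whose pure-noise error s.d. targets a given repeatability.

    Blunders, heaping and the between-team offset are switched off so that
    the correlation between the two measurements is governed by classical
    error alone; at reliability 1 the two measurements coincide exactly.
    The trait variance entering the calibration is the analytic variance of
    the true liability under ``base``.
    """
    var_y = base.sigma2_a + base.sigma2_e + base.herd_sd**2 + base.ssg_sd**2
    for q in base.qtl_specs:
        var_y += 2.0 * q.freq * (1.0 - q.freq) * q.effect_mm**2
    sigma = 0.0 if reliability >= 1.0 else calibrate_error_sd(reliability, var_y)
    return replace(
        base,
        seed=base.seed if seed is None else seed,
        sigma_small=sigma,
        blunder_prob=0.0,
        heaping_prob=0.0,
        offset_delta=0.0,
    )
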