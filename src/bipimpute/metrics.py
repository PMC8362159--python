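"""Imputation accuracy and yield, plus the scenario replication harness.

Accuracy is the Pearson correlation between true and imputed genotype
codes over the markers actually imputed (imputed != 9); yield is the
fraction of high-density markers with a non-missing imputed genotype.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypePair, ScenarioSpec
from .parent import impute_parents
from .phasing import impute_descendant
from .sim import SimulatedPopulation, build_scenario, replicate_rngs


def accuracy(true_row: np.ndarray, imputed_row: np.ndarray) -> float:
    """Pearson correlation of true vs imputed genotypes over imputed loci.

    Returns NaN when either vector is constant on the compared loci (the
    correlation is undefined there).
    """
    true_row = np.asarray(true_row)
    imputed_row = np.asarray(imputed_row)
    if true_row.shape != imputed_row.shape:
        raise ValueError("row length mismatch")
    mask = (imputed_row != MISSING) & (true_row != MISSING)
    if mask.sum() < 2:
        return float("nan")
    t = true_row[mask].astype(float)
    i = imputed_row[mask].astype(float)
    if np.ptp(t) == 0 or np.ptp(i) == 0:
        return float("nan")
    return float(np.corrcoef(t, i)[0, 1])


def yield_(imputed_row: np.ndarray, n_hd: int) -> float:
    """Fraction of the high-density panel with an imputed genotype."""
    if n_hd == 0:
        raise ValueError("empty panel")
    imputed_row = np.asarray(imputed_row)
    return float(np.sum(imputed_row != MISSING) / n_hd)


def run_replicate(
    spec: ScenarioSpec,
    rng: np.random.Generator | int | None = None,
    evaluate_focal: bool = False,
    max_focal_per_cross: int | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Simulate one replicate, impute Parent A, and score it.

    With ``evaluate_focal`` the low-density focal F2 are additionally
    imputed twice — against the true phased Parent A and against the
    imputed one — and their mean accuracies reported.
    """
    sim = build_scenario(spec, rng)
    results, _ = impute_parents(
        sim.genotypes_masked, sim.pedigree, sim.panel, alpha=alpha
    )
    a_true = sim.true_genotype("A")
    res = results.get("A")
    if res is None:
        imputed_geno = np.full(a_true.shape, MISSING, dtype=np.int8)
        imputed_pair = HaplotypePair(imputed_geno.copy(), imputed_geno.copy())
    else:
        imputed_geno = res.genotypes
        imputed_pair = res.haplotypes
    out = {
        "parent_accuracy": accuracy(a_true, imputed_geno),
        "parent_yield": yield_(imputed_geno, sim.panel.n_markers),
    }
    if evaluate_focal:
        out.update(
            _focal_accuracies(sim, imputed_pair, max_focal_per_cross)
        )
    return out


def _focal_accuracies(
    sim: SimulatedPopulation,
    imputed_parent: HaplotypePair,
    max_focal_per_cross: int | None,
) -> dict[str, float]:
    pos = sim.panel.positions_cm
    true_parent = sim.true_haplotypes["A"]
    acc_true, acc_imp = [], []
    for mate in sim.mates:
        mate_pair = HaplotypePair.from_genotypes(
            sim.genotypes_masked.row(mate)
        )
        focals = sim.focal_individuals[mate]
        if max_focal_per_cross is not None:
            focals = focals[:max_focal_per_cross]
        for f in focals:
            observed = sim.genotypes_masked.row(f)
            truth = sim.true_genotype(f)
            for parent_pair, sink in (
                (true_parent, acc_true),
                (imputed_parent, acc_imp),
            ):
                imp = impute_descendant(observed, parent_pair, mate_pair, pos)
                sink.append(accuracy(truth, imp.genotypes))
    return {
        "focal_accuracy_true_parent": float(np.nanmean(acc_true)),
        "focal_accuracy_imputed_parent": float(np.nanmean(acc_imp)),
    }


def run_scenarios(
    specs: Sequence[tuple[str, ScenarioSpec]] | Sequence[ScenarioSpec],
    evaluate_focal: bool = False,
    max_focal_per_cross: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate each scenario and tabulate mean and SD of each metric.

    ``specs`` is a sequence of ScenarioSpec (labelled automatically) or
    of (label, spec) pairs.  Each spec's own ``n_replicates`` and
    ``seed`` drive the replication; results are fully reproducible.
    """
    rows = []
    for item in specs:
        label, spec = item if isinstance(item, tuple) else (None, item)
        if label is None:
            label = (
                f"{spec.n_crosses}x_"
                f"{'inbred' if spec.parentA_inbred else 'outbred'}_"
                f"{spec.parentA_genotyping}"
                f"{'_gp' if spec.include_grandparents else ''}"
            )
        reps = []
        for rng in replicate_rngs(spec):
            reps.append(
                run_replicate(
                    spec,
                    rng,
                    evaluate_focal=evaluate_focal,
                    max_focal_per_cross=max_focal_per_cross,
                    alpha=alpha,
                )
            )
        rep_df = pd.DataFrame(reps)
        row: dict[str, object] = {
            "scenario": label,
            "n_crosses": spec.n_crosses,
            "inbred": spec.parentA_inbred,
            "genotyping": spec.parentA_genotyping,
            "grandparents": spec.include_grandparents,
            "n_replicates": spec.n_replicates,
        }
        for col in rep_df.columns:
            row[f"{col}_mean"] = float(rep_df[col].mean())
            row[f"{col}_sd"] = float(rep_df[col].std(ddof=1))
        if evaluate_focal:
            gaps = (
                rep_df["focal_accuracy_true_parent"]
                - rep_df["focal_accuracy_imputed_parent"]
            )
            row["focal_accuracy_gap_mean"] = float(gaps.mean())
            row["focal_accuracy_gap_sd"] = float(gaps.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
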