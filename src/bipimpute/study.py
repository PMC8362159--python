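"""Desk-scale replication of the validation study conditions.

The original study runs 100 replicates of 25,000-SNP, 1,000-F2
populations.  All reported effects are large relative to their
replicate SDs, so the study is reproducible at desk scale by reducing
the marker count, family size and replicate count while keeping the
design fixed: a 1-Morgan chromosome, 50 Ld SNPs, 10 (or 50)
high-density descendants per cross.  This module runs that scaled study
and summarises parent accuracy, parent yield and the focal-F2 accuracy
comparison per condition.
"""

from __future__ import annotations

import numpy as np

from .core import ScenarioSpec
from .metrics import run_replicate

#: desk-scale defaults: 2,000 Hd SNPs, 200 F2 per cross, 20 replicates
DESK_SCALE = dict(
    n_hd_snps=2000,
    n_ld_snps=50,
    n_f2_per_cross=200,
    n_base_sites=12000,
)

#: the study conditions, in presentation order
CONDITIONS: list[tuple[str, dict, bool]] = [
    ("one_cross_inbred_ungenotyped",
     dict(n_crosses=1, parentA_inbred=True, parentA_genotyping="none"), False),
    ("one_cross_outbred_ungenotyped",
     dict(n_crosses=1, parentA_inbred=False, parentA_genotyping="none"), True),
    ("one_cross_inbred_ld",
     dict(n_crosses=1, parentA_inbred=True, parentA_genotyping="ld"), False),
    ("grandparents_outbred_ld",
     dict(n_crosses=1, parentA_inbred=False, parentA_genotyping="ld",
          include_grandparents=True), False),
    ("two_crosses_inbred_ungenotyped",
     dict(n_crosses=2, parentA_inbred=True, parentA_genotyping="none"), False),
    ("four_crosses_outbred_ungenotyped",
     dict(n_crosses=4, parentA_inbred=False, parentA_genotyping="none"), False),
    ("fifty_hd_outbred_ungenotyped",
     dict(n_crosses=1, parentA_inbred=False, parentA_genotyping="none",
          n_hd_descendants_per_cross=50), False),
]


def run_condition(
    name: str,
    spec_kwargs: dict,
    seed_sequence: np.random.SeedSequence,
    n_replicates: int,
    evaluate_focal: bool,
    scale: dict | None = None,
) -> dict[str, float]:
    """Replicate one condition and summarise its metrics."""
    scale = dict(DESK_SCALE if scale is None else scale)
    spec = ScenarioSpec(**{**scale, **spec_kwargs, "n_replicates": n_replicates})
    rows = [
        run_replicate(spec, np.random.default_rng(child),
                      evaluate_focal=evaluate_focal)
        for child in seed_sequence.spawn(n_replicates)
    ]
    out: dict[str, float] = {"condition": name, "n_replicates": n_replicates}
    for key in rows[0]:
        vals = np.array([r[key] for r in rows], dtype=float)
        out[f"{key}_mean"] = float(np.nanmean(vals))
        out[f"{key}_sd"] = float(np.nanstd(vals, ddof=1))
    if evaluate_focal:
        gaps = np.array([
            r["focal_accuracy_true_parent"] - r["focal_accuracy_imputed_parent"]
            for r in rows
        ])
        out["focal_accuracy_gap_mean"] = float(np.nanmean(gaps))
        out["focal_accuracy_gap_sd"] = float(np.nanstd(gaps, ddof=1))
    return out


def desk_scale_study(
    seed: int,
    n_replicates: int = 60,
    focal_replicates: int | None = 100,
    scale: dict | None = None,
) -> dict[str, dict[str, float]]:
    """Run every study condition at desk scale with independent,
    reproducible random streams derived from one seed.

    The focal-imputation comparison has the noisiest replicate
    distribution (its gap is dominated by occasional hard-to-impute
    parents), so that condition defaults to more replicates.
    """
    streams = np.random.SeedSequence(seed).spawn(len(CONDITIONS))
    out = {}
    for (name, kwargs, focal), stream in zip(CONDITIONS, streams):
        reps = focal_replicates if (focal and focal_replicates) else n_replicates
        out[name] = run_condition(name, kwargs, stream, reps, focal, scale)
    return out
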