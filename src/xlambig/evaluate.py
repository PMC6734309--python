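"""Model quality and scoring-function benchmarks for homo-dimer docking.

A docking model is near-native when its Cα-RMSD to the recreated reference
is at or below 10 Å, with the RMSD minimized over the two possible chain
mappings (the two chains are identical, so their labels are arbitrary).
A scoring function's precision on one structure is the percentage of
near-native models among its top-10 ranked models; benchmarks aggregate
precision as mean ± SEM over structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sasd_engine
from .scoring import ModelScore, ScoringConfig, model_candidates, rank_models, score_model
from .simulate import generate_decoys, simulate_crosslinks
from .structio import Structure, ValidationError, kabsch_superpose, recreate_reference

logger = logging.getLogger(__name__)

__all__ = [
    "PrecisionResult",
    "BenchmarkReport",
    "ca_rmsd",
    "precision_at_k",
    "run_benchmark",
]


def _chain_ca(structure: Structure, chain_id: str) -> dict:
    chain = structure.chain(chain_id)
    out = {}
    for res in chain.residues:
        ca = res.atom("CA")
        if ca is not None:
            out[res.key] = ca.pos
    return out


def ca_rmsd(model: Structure, reference: Structure) -> float:
    """Whole-complex Cα-RMSD after optimal superposition, minimized over
    the two homo-dimer chain mappings (A→A,B→B and A→B,B→A)."""
    if len(model.chains) != 2 or len(reference.chains) != 2:
        raise ValidationError("ca_rmsd expects two-chain structures")
    m1, m2 = model.chain_ids
    r1, r2 = reference.chain_ids
    mcas = {cid: _chain_ca(model, cid) for cid in (m1, m2)}
    rcas = {cid: _chain_ca(reference, cid) for cid in (r1, r2)}
    best = None
    for mapping in ((r1, r2), (r2, r1)):
        P, Q = [], []
        for mc, rc in zip((m1, m2), mapping):
            if set(mcas[mc]) != set(rcas[rc]):
                raise ValidationError(
                    f"chain {mc} and {rc} differ in Cα residue composition"
                )
            for key in sorted(mcas[mc]):
                P.append(mcas[mc][key])
                Q.append(rcas[rc][key])
        _, rmsd = kabsch_superpose(np.asarray(P), np.asarray(Q))
        best = rmsd if best is None else min(best, rmsd)
    return float(best)


@dataclass
class PrecisionResult:
    structure_id: str
    config_label: str
    precision: float  # percent of near-native among top-k
    k: int
    cutoff: float
    per_model: pd.DataFrame  # rank, model_id, total, rmsd, near_native


def precision_at_k(
    ranked_models: list[ModelScore],
    rmsds: dict[str, float],
    structure_id: str = "",
    config_label: str = "",
    k: int = 10,
    cutoff: float = 10.0,
) -> PrecisionResult:
    """Percentage of near-native models among the top-k of a ranking.

    ``rmsds`` maps model id to Cα-RMSD against the recreated reference.
    With fewer than k models the denominator is the model count.
    """
    if not ranked_models:
        raise ValidationError("empty ranking")
    rows = []
    for rank, ms in enumerate(ranked_models, start=1):
        rmsd = float(rmsds[ms.model_id])
        rows.append(
            {
                "rank": rank,
                "model_id": ms.model_id,
                "total": ms.total,
                "rmsd": rmsd,
                "near_native": rmsd <= cutoff,
            }
        )
    df = pd.DataFrame(rows)
    top = df.head(k)
    precision = 100.0 * top["near_native"].sum() / min(k, len(df))
    return PrecisionResult(structure_id, config_label, float(precision), k, cutoff, df)


@dataclass
class BenchmarkReport:
    per_structure: pd.DataFrame  # structure, config, precision
    summary: pd.DataFrame  # config, mean, sem, n
    excluded: list[str] = field(default_factory=list)
    results: list[PrecisionResult] = field(default_factory=list)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def run_benchmark(
    references: list[Structure],
    configs: list[ScoringConfig],
    n_models: int = 200,
    near_native_fraction: float = 0.1,
    threshold: float = 33.0,
    k: int = 10,
    cutoff: float = 10.0,
    seed: int = 0,
    grid_spacing: float = 1.0,
) -> BenchmarkReport:
    """Score decoy ensembles for every reference under every configuration.

    Per reference: recreate the dimer, simulate cross-links from its surface
    distances, generate a seeded decoy ensemble, score every model under
    each configuration and record top-k precision. References yielding no
    simulated cross-links, or fewer than ten near-native decoys, are
    excluded (benchmarking precision against a structure the ensemble
    cannot approximate is meaningless).

    Distances are computed once per model and method and shared across all
    configurations using that method. Fully deterministic for a fixed seed.
    """
    if len(references) < 1 or len(configs) < 1:
        raise ValidationError("need at least one reference and one config")
    rng = np.random.default_rng(seed)
    struct_seeds = rng.integers(0, 2**31 - 1, size=len(references))
    methods = sorted({c.method.upper() for c in configs})
    rows = []
    excluded = []
    results = []
    for ref_raw, sseed in zip(references, struct_seeds):
        ref = recreate_reference(ref_raw)
        ref_grid = sasd_engine.build_grid(ref, spacing=grid_spacing)
        xls = simulate_crosslinks(ref, threshold=threshold, grid=ref_grid)
        if len(xls) == 0:
            excluded.append(ref.name)
            logger.info("excluding %s: no simulated cross-links", ref.name)
            continue
        ensemble = generate_decoys(
            ref,
            n_models=n_models,
            near_native_fraction=near_native_fraction,
            seed=int(sseed),
        )
        models = [ensemble.model(i) for i in range(ensemble.count)]
        rmsds = {m.name: ca_rmsd(m, ref) for m in models}
        n_near = sum(1 for v in rmsds.values() if v <= cutoff)
        if n_near < 10:
            excluded.append(ref.name)
            logger.info("excluding %s: only %d near-native decoys", ref.name, n_near)
            continue
        # distance tables once per model and method, shared by all configs.
        # Any distance beyond threshold + symmetry cutoff scores identically
        # (penalty branch), so the surface-path search can stop there.
        sym_cut = max(c.params.symmetry_difference_cutoff for c in configs)
        path_limit = threshold + sym_cut + 1.0
        cand_cache = {}
        for method in methods:
            per_model = []
            for m in models:
                grid = (
                    sasd_engine.build_grid(m, spacing=grid_spacing)
                    if method == "SASD"
                    else None
                )
                per_model.append(
                    model_candidates(
                        list(xls.pairs), m, method=method, grid=grid,
                        path_limit=path_limit,
                    )
                )
            cand_cache[method] = per_model
        for config in configs:
            cands = cand_cache[config.method.upper()]
            scores = [
                score_model(list(xls.pairs), m, config, candidates=c)
                for m, c in zip(models, cands)
            ]
            ranked = rank_models(scores)
            res = precision_at_k(
                ranked, rmsds, structure_id=ref.name, config_label=config.label,
                k=k, cutoff=cutoff,
            )
            results.append(res)
            rows.append(
                {"structure": ref.name, "config": config.label, "precision": res.precision}
            )
    per_structure = pd.DataFrame(rows, columns=["structure", "config", "precision"])
    summary_rows = []
    for config in configs:
        vals = per_structure.loc[per_structure["config"] == config.label, "precision"].to_numpy()
        summary_rows.append(
            {
                "config": config.label,
                "mean_precision": float(np.mean(vals)) if len(vals) else float("nan"),
                "sem": _sem(vals),
                "n_structures": int(len(vals)),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return BenchmarkReport(per_structure, summary, excluded, results)
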