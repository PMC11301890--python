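"""Divide-and-conquer fitting: partition subjects, fit chunks, pool.

Large cohorts are split into disjoint subject chunks, each chunk is fitted
by the full MCMC sampler, and the chunk-level posterior summaries are
combined into one pooled estimate. Two pooling rules are offered:

* ``mean_se`` (default): the pooled mean is the simple average of chunk
  means; the pooled variance is (1/K^2) * sum of chunk variances, the
  combination rule for independent chunk estimates, so pooled uncertainty
  shrinks like the full-data fit's;
* ``precision_weighted``: chunks are combined by their inverse posterior
  covariance matrices H_k, pooled theta = (sum H_k)^-1 sum H_k m_k —
  mirroring a Hessian-accumulation update.

The spline basis for the baseline hazard is placed once on the full event
set and shared by every chunk, so the baseline coefficients are
commensurable across chunks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SplineBasis, place_knots
from .data_io import (
    LongitudinalData,
    SurvivalData,
    ValidatedDataset,
    validate_join,
)
from .likelihood import ModelData, ModelSpec, PriorSpec
from .mcmc import FitSummary, McmcConfig, PosteriorDraws, fit_mcmc, summarize_draws

__all__ = [
    "ChunkPartition",
    "ChunkFit",
    "PooledFit",
    "split_subjects",
    "pool_mean_se",
    "pool_precision_weighted",
    "fit_big",
]

#: smallest chunk a fit will accept; configurable via split_subjects(floor=...)
DEFAULT_CHUNK_FLOOR = 20


@dataclass(frozen=True)
class ChunkPartition:
    chunks: tuple[tuple, ...]  # tuples of subject ids, pairwise disjoint
    chunk_size: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.chunks)


@dataclass
class ChunkFit:
    index: int
    summary: FitSummary
    draws: PosteriorDraws | None = None
    covariance: pd.DataFrame | None = None


@dataclass
class PooledFit:
    """Pooled parameter estimates across chunks."""

    mean: pd.Series
    se: pd.Series
    k: int
    chunk_size: int
    pooling_method: str
    n_subjects: int
    chunk_fits: list[ChunkFit] = field(default_factory=list)
    basis: SplineBasis | None = None
    b_mean: np.ndarray | None = None  # per-subject posterior-mean random effects
    subject_ids: np.ndarray | None = None


def split_subjects(
    ids, chunk_size: int, seed: int, floor: int = DEFAULT_CHUNK_FLOOR
) -> ChunkPartition:
    """Shuffle ids and slice into consecutive chunks of ``chunk_size``.

    A trailing chunk smaller than max(floor, chunk_size/2) is merged into
    its predecessor, so no fit ever sees a degenerately small chunk.
    """
    if chunk_size < floor:
        raise ValueError(f"chunk_size {chunk_size} below the floor of {floor}")
    ids = np.asarray(list(ids))
    rng = np.random.default_rng(seed)
    perm = ids[rng.permutation(len(ids))]
    chunks = [perm[i : i + chunk_size] for i in range(0, len(perm), chunk_size)]
    min_last = max(floor, chunk_size // 2)
    if len(chunks) > 1 and len(chunks[-1]) < min_last:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    return ChunkPartition(
        chunks=tuple(tuple(c) for c in chunks), chunk_size=chunk_size, seed=seed
    )


def _check_consistent(chunks: list[ChunkFit]) -> pd.Index:
    if not chunks:
        raise ValueError("no chunk fits to pool")
    names = chunks[0].summary.table.index
    for c in chunks[1:]:
        if not c.summary.table.index.equals(names):
            extra = set(c.summary.table.index) ^ set(names)
            raise ValueError(f"inconsistent parameter lists across chunks: {sorted(extra)}")
    return names


def pool_mean_se(chunks: list[ChunkFit]) -> PooledFit:
    """Average chunk means; pooled variance = (1/K^2) sum of chunk variances."""
    names = _check_consistent(chunks)
    k = len(chunks)
    means = np.stack([c.summary.table["mean"].to_numpy() for c in chunks])
    sds = np.stack([c.summary.table["sd"].to_numpy() for c in chunks])
    pooled_mean = means.mean(axis=0)
    pooled_se = np.sqrt((sds**2).sum(axis=0)) / k
    n_total = sum(c.summary.n_subjects for c in chunks)
    return PooledFit(
        mean=pd.Series(pooled_mean, index=names),
        se=pd.Series(pooled_se, index=names),
        k=k,
        chunk_size=max(c.summary.n_subjects for c in chunks),
        pooling_method="mean_se",
        n_subjects=n_total,
        chunk_fits=list(chunks),
    )


def pool_precision_weighted(chunks: list[ChunkFit]) -> PooledFit:
    """Combine chunks by inverse-covariance weights (Hessian accumulation)."""
    names = _check_consistent(chunks)
    h_sum = None
    hm_sum = None
    for c in chunks:
        if c.covariance is None:
            raise ValueError(f"chunk {c.index} carries no parameter covariance")
        cov = c.covariance.loc[names, names].to_numpy()
        try:
            h = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"chunk {c.index} has a singular parameter covariance"
            ) from exc
        m = c.summary.table["mean"].to_numpy()
        h_sum = h if h_sum is None else h_sum + h
        hm_sum = h @ m if hm_sum is None else hm_sum + h @ m
    pooled_cov = np.linalg.inv(h_sum)
    pooled_mean = pooled_cov @ hm_sum
    n_total = sum(c.summary.n_subjects for c in chunks)
    return PooledFit(
        mean=pd.Series(pooled_mean, index=names),
        se=pd.Series(np.sqrt(np.diag(pooled_cov)), index=names),
        k=len(chunks),
        chunk_size=max(c.summary.n_subjects for c in chunks),
        pooling_method="precision_weighted",
        n_subjects=n_total,
        chunk_fits=list(chunks),
    )


def _subset(long: LongitudinalData, surv: SurvivalData, ids) -> ValidatedDataset:
    idset = set(ids)
    long_sub = long.records[long.records["subject_id"].isin(idset)].reset_index(drop=True)
    surv_sub = surv.records[surv.records["subject_id"].isin(idset)].reset_index(drop=True)
    from dataclasses import replace

    return validate_join(
        replace(long, records=long_sub), replace(surv, records=surv_sub)
    )


def fit_big(
    long: LongitudinalData,
    surv: SurvivalData,
    spec: ModelSpec | None = None,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    chunk_size: int = 1000,
    pooling_method: str = "mean_se",
    seed: int = 0,
    n_knots: int = 2,
    keep_draws: bool = False,
) -> PooledFit:
    """Validate, split, fit every chunk, and pool.

    Knots are placed on the full event-time set so all chunks share one
    baseline-hazard basis; chunk k is fitted with seed ``seed + 1 + k`` so
    runs are reproducible and independent of processing order. A chunk
    without any events is merged into the following chunk before fitting.
    """
    spec = spec or ModelSpec()
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig(seed=seed)
    if pooling_method not in ("mean_se", "precision_weighted"):
        raise ValueError(f"unknown pooling_method {pooling_method!r}")

    ds = validate_join(long, surv)
    ev = surv.records.loc[surv.records["event"] == 1, "observed_time"].to_numpy()
    basis = place_knots(ev, n_knots)

    part = split_subjects(
        ds.survival.subject_ids,
        min(chunk_size, ds.n_subjects),
        seed,
        floor=min(DEFAULT_CHUNK_FLOOR, ds.n_subjects),
    )
    ev_by_id = surv.records.set_index("subject_id")["event"]

    # merge event-free chunks forward so every fitted chunk has >= 1 event
    pending: list[np.ndarray] = []
    merged: list[np.ndarray] = []
    for chunk in part.chunks:
        cur = np.asarray(chunk)
        if pending:
            cur = np.concatenate([pending.pop(), cur])
        if ev_by_id.loc[list(cur)].sum() == 0:
            pending.append(cur)
        else:
            merged.append(cur)
    if pending:
        if not merged:
            raise ValueError("no events anywhere in the data; cannot fit")
        merged[-1] = np.concatenate([merged[-1], pending.pop()])

    chunk_fits: list[ChunkFit] = []
    b_blocks: dict = {}
    for k, chunk_ids in enumerate(merged):
        sub = _subset(ds.longitudinal, ds.survival, chunk_ids)
        cfg = McmcConfig(
            n_iter=mcmc.n_iter,
            n_burnin=mcmc.n_burnin,
            thin=mcmc.thin,
            seed=seed + 1 + k,
            step_scales=dict(mcmc.step_scales),
            adapt=mcmc.adapt,
            keep_random_effects=mcmc.keep_random_effects,
        )
        md = ModelData(sub, spec, basis)
        draws = fit_mcmc(sub, spec, priors, basis, cfg, _md=md)
        summary = summarize_draws(draws)
        cov = draws.covariance() if pooling_method == "precision_weighted" else None
        chunk_fits.append(
            ChunkFit(
                index=k,
                summary=summary,
                draws=draws if keep_draws else None,
                covariance=cov,
            )
        )
        for sid, brow in zip(md.ids, draws.b_mean):
            b_blocks[sid] = brow

    if pooling_method == "mean_se":
        pooled = pool_mean_se(chunk_fits)
    else:
        pooled = pool_precision_weighted(chunk_fits)
    pooled.chunk_size = min(chunk_size, ds.n_subjects)
    pooled.basis = basis
    all_ids = ds.survival.subject_ids
    pooled.subject_ids = all_ids
    pooled.b_mean = np.stack([b_blocks[sid] for sid in all_ids])
    return pooled
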