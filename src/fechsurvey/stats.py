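"""Cysteine/motif statistics and physiology cross-tabulations.

Covers the survey's numerical analyses: per-sequence cysteine profiles,
binned motif likelihood with plain binomial standard errors
(sqrt(p(1-p)/n)), a binary logistic regression of motif presence on
cysteine count fitted by iteratively reweighted least squares (IRLS) with
Wald confidence intervals on the odds-ratio scale, and the species-level
cross-tabulations of MCF status against taxonomy, habitat, growth
temperature, oxygen requirement and ferredoxin (COG0633) presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from fechsurvey.io_metadata import (
    Dataset,
    OXYGEN_LEVELS,
    ProteinRecord,
    TEMP_RANGES,
)

DEFAULT_CYS_BINS = ((0, 3), (4, 5), (6, 10), (11, None))


@dataclass(frozen=True)
class CysteineProfile:
    record_id: str
    cys_count: int
    cys_fraction: float
    length: int


@dataclass(frozen=True)
class BinLikelihood:
    """Motif likelihood within one cysteine-count bin.

    p_hat = k/n with binomial standard error sqrt(p_hat(1-p_hat)/n);
    an empty bin reports NaN for both.
    """

    bin_lo: int
    bin_hi: int | None  # None = open-ended
    n: int
    k: int
    p_hat: float
    se: float


@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression result (single covariate).

    odds_ratio = exp(beta1): multiplicative change in the odds of motif
    presence per additional cysteine. ci95 is the Wald interval
    exp(beta1 +/- 1.96 se1).
    """

    beta0: float
    beta1: float
    se0: float
    se1: float
    odds_ratio: float
    ci95: tuple[float, float]
    converged: bool
    iterations: int
    log_likelihood: float


def cysteine_profile(record: ProteinRecord) -> CysteineProfile:
    """Count cysteines in the (trimmed) sequence."""
    seq = record.trimmed_sequence
    count = seq.count("C")
    return CysteineProfile(
        record_id=record.record_id,
        cys_count=count,
        cys_fraction=count / len(seq),
        length=len(seq),
    )


def binned_likelihood(
    profiles: Sequence[CysteineProfile],
    mcf_labels: Mapping[str, bool],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_CYS_BINS,
) -> list[BinLikelihood]:
    """Per-bin motif probability and binomial SE.

    ``bins`` are inclusive integer intervals on the cysteine count; an
    upper bound of None is open-ended. Bins must be disjoint.
    """
    edges = []
    for lo, hi in bins:
        hi_eff = math.inf if hi is None else hi
        if hi_eff < lo:
            raise ValueError(f"bad bin ({lo}, {hi})")
        edges.append((lo, hi_eff))
    for (a1, b1), (a2, b2) in zip(edges, edges[1:]):
        if a2 <= b1 and a1 <= b2:
            raise ValueError("bins overlap")
    out = []
    for (lo, hi), (lo_raw, hi_raw) in zip(edges, bins):
        members = [p for p in profiles if lo <= p.cys_count <= hi]
        n = len(members)
        k = sum(1 for p in members if mcf_labels[p.record_id])
        if n == 0:
            out.append(BinLikelihood(lo_raw, hi_raw, 0, 0, float("nan"), float("nan")))
        else:
            p_hat = k / n
            out.append(
                BinLikelihood(
                    lo_raw, hi_raw, n, k, p_hat, math.sqrt(p_hat * (1 - p_hat) / n)
                )
            )
    return out


def logistic_fit(
    x: Sequence[float],
    y: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Fit P(y=1|x) = 1/(1+exp(-(b0+b1 x))) by IRLS (Newton-Raphson).

    Standard errors come from the inverse observed information at the
    optimum. Complete separation (or any failure to converge within
    ``max_iter``) is reported via ``converged=False`` rather than raised.
    Requires both outcome classes present and a non-constant covariate.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if not (np.any(yv == 0) and np.any(yv == 1)):
        raise ValueError("both outcome classes must be present")
    if np.ptp(xv) == 0:
        raise ValueError("covariate is constant")

    X = np.column_stack([np.ones_like(xv), xv])
    beta = np.zeros(2)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step: beta += (X'WX)^-1 X'(y - mu)
        info = X.T @ (X * w[:, None])
        score = X.T @ (yv - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se0, se1 = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        se0 = se1 = float("nan")
    ll = float(np.sum(special.xlogy(yv, mu) + special.xlogy(1 - yv, 1 - mu)))

    def _exp(v: float) -> float:
        return math.inf if v > 700 else math.exp(v)

    orx = _exp(beta[1])
    ci = (_exp(beta[1] - 1.96 * se1), _exp(beta[1] + 1.96 * se1))
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se0=se0,
        se1=se1,
        odds_ratio=orx,
        ci95=ci,
        converged=converged,
        iterations=iterations,
        log_likelihood=ll,
    )


def round_percent(value: float) -> int:
    """Nearest whole percent, halves rounded up (table convention)."""
    return int(math.floor(value * 100 + 0.5))


def species_mcf_status(
    dataset: Dataset, mcf_by_record: Mapping[str, bool]
) -> dict[str, bool]:
    """Collapse record-level MCF calls to species (genome) level.

    A genome counts as MCF-containing when any of its records is MCF
    (duplicate-ferrochelatase genomes with one motif copy still count).
    """
    status = {gid: False for gid in dataset.genomes}
    for rec in dataset.records:
        if mcf_by_record.get(rec.record_id, False):
            status[rec.genome_id] = True
    return status


def crosstab(
    dataset: Dataset,
    mcf_by_record: Mapping[str, bool],
    field: str,
    denominator: str = "per_row_total",
) -> pd.DataFrame:
    """Cross-tabulate species-level MCF status against a metadata field.

    ``denominator='per_row_total'`` reports percent = mcf/total within
    each category row (taxon-table style); ``'mcf_total'`` reports
    percent = category MCF count / total MCF count (habitat-table style).
    Percentages are rounded to the nearest whole percent, halves up.
    """
    if denominator not in {"per_row_total", "mcf_total"}:
        raise ValueError(f"unknown denominator {denominator!r}")
    status = species_mcf_status(dataset, mcf_by_record)
    rows: dict[str, dict[str, int]] = {}
    for gid, meta in dataset.genomes.items():
        cat = getattr(meta, field)
        cell = rows.setdefault(str(cat), {"total": 0, "mcf": 0})
        cell["total"] += 1
        if status[gid]:
            cell["mcf"] += 1
    total_mcf = sum(c["mcf"] for c in rows.values())
    table = []
    for cat in sorted(rows):
        c = rows[cat]
        if denominator == "per_row_total":
            pct = round_percent(c["mcf"] / c["total"]) if c["total"] else 0
        else:
            pct = round_percent(c["mcf"] / total_mcf) if total_mcf else 0
        table.append(
            {"category": cat, "total": c["total"], "mcf": c["mcf"], "percent": pct}
        )
    return pd.DataFrame(table, columns=["category", "total", "mcf", "percent"])


def environment_group_shares(env_crosstab: pd.DataFrame) -> dict[str, int]:
    """Aggregate an environment cross-tab into top-level habitat groups.

    Sums MCF counts over the aquatic/terrestrial/host/industry
    subcategories and reports each group's share of all MCF species as a
    whole percent (halves up). Input is a ``crosstab(...,
    field='environment')`` table (either denominator; raw counts are
    used).
    """
    groups = ("aquatic", "terrestrial", "host", "industry", "other", "no_data")
    mcf_by_group = {g: 0 for g in groups}
    total_mcf = int(env_crosstab["mcf"].sum())
    for _, row in env_crosstab.iterrows():
        cat = str(row["category"])
        group = next((g for g in groups if cat == g or cat.startswith(g + "_")), None)
        if group is None:
            raise ValueError(f"unrecognized environment category {cat!r}")
        mcf_by_group[group] += int(row["mcf"])
    if total_mcf == 0:
        return {g: 0 for g in groups}
    return {g: round_percent(k / total_mcf) for g, k in mcf_by_group.items()}


def gc_summary(
    dataset: Dataset,
    mcf_by_record: Mapping[str, bool],
    location_by_record: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Mean GC% for all / MCF / non-MCF species, and by motif location.

    ``location_by_record`` maps record id to the qualifying motif location
    ("insertion" / "c_terminal"); when given, per-location species means
    are included.
    """
    status = species_mcf_status(dataset, mcf_by_record)
    gc = {
        gid: m.gc_percent
        for gid, m in dataset.genomes.items()
        if m.gc_percent == m.gc_percent
    }

    def mean_of(gids: Iterable[str]) -> float:
        vals = [gc[g] for g in gids if g in gc]
        return float(np.mean(vals)) if vals else float("nan")

    out = {
        "all": mean_of(gc),
        "mcf": mean_of(g for g, s in status.items() if s),
        "non_mcf": mean_of(g for g, s in status.items() if not s),
    }
    if location_by_record is not None:
        loc_genomes: dict[str, set[str]] = {"insertion": set(), "c_terminal": set()}
        for rec in dataset.records:
            loc = location_by_record.get(rec.record_id)
            if loc in loc_genomes:
                loc_genomes[loc].add(rec.genome_id)
        out["mcf_insertion"] = mean_of(loc_genomes["insertion"])
        out["mcf_c_terminal"] = mean_of(loc_genomes["c_terminal"])
    return out


def cooccurrence(
    dataset: Dataset, mcf_by_record: Mapping[str, bool]
) -> pd.DataFrame:
    """Ferredoxin (COG0633) x MCF co-occurrence by oxygen requirement.

    Four mutually exclusive cells per oxygen class (neither, cog_only,
    mcf_only, both); cells sum to the class census.
    """
    status = species_mcf_status(dataset, mcf_by_record)
    counts = {
        lvl: {"neither": 0, "cog_only": 0, "mcf_only": 0, "both": 0}
        for lvl in OXYGEN_LEVELS
    }
    for gid, meta in dataset.genomes.items():
        mcf = status[gid]
        cog = meta.has_cog0633
        if mcf and cog:
            cell = "both"
        elif mcf:
            cell = "mcf_only"
        elif cog:
            cell = "cog_only"
        else:
            cell = "neither"
        counts[meta.oxygen_req][cell] += 1
    return pd.DataFrame(
        [
            {"oxygen_req": lvl, **counts[lvl]}
            for lvl in OXYGEN_LEVELS
        ],
        columns=["oxygen_req", "neither", "cog_only", "mcf_only", "both"],
    )


def temperature_table(
    dataset: Dataset, mcf_by_record: Mapping[str, bool]
) -> pd.DataFrame:
    """Species totals and MCF counts by growth-temperature class."""
    status = species_mcf_status(dataset, mcf_by_record)
    counts = {lvl: {"total": 0, "mcf": 0} for lvl in TEMP_RANGES}
    for gid, meta in dataset.genomes.items():
        counts[meta.temp_range]["total"] += 1
        if status[gid]:
            counts[meta.temp_range]["mcf"] += 1
    return pd.DataFrame(
        [{"temp_range": lvl, **counts[lvl]} for lvl in TEMP_RANGES],
        columns=["temp_range", "total", "mcf"],
    )


def length_cys_correlation(
    profiles: Sequence[CysteineProfile],
) -> tuple[float, bool]:
    """Pearson r between sequence length and cysteine count.

    Returns ``(r, defined)``; ``defined`` is False (r = NaN) when either
    variable is constant.
    """
    lengths = np.array([p.length for p in profiles], dtype=float)
    counts = np.array([p.cys_count for p in profiles], dtype=float)
    if len(profiles) < 2 or np.ptp(lengths) == 0 or np.ptp(counts) == 0:
        return float("nan"), False
    r = sps.pearsonr(lengths, counts).statistic
    return float(r), True
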