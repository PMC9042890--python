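"""Two-dimensional enrichment statistics.

The analysis couples two continuous axes — per-element log2 fold changes
(FC) from the data and network influence scores (I) from the map — into
per-element enrichment statistics:

* downstream (phenotype) inference: ``Level = sum I*FC`` estimates the
  change in phenotype activity, ``Saturation`` the influence-weighted
  fraction of the phenotype's regulators present in the data, and the
  enrichment score ``ES = sum(|I*FC| * I*FC) / (k + sum(I^2 * FC^2))``
  measures how strongly the (I, FC) cloud leans towards concordant
  (positive) or discordant (negative) regulation.  ``ES`` equals the slope
  of a least-squares line through the origin after projecting every point
  onto the diagonals — x = FC*|I|, y = |FC|*I — with baseline points of
  total x^2-mass ``k`` (default 2: the points (1,0) and (-1,0)) pulling the
  slope towards zero, so |ES| <= 1 always.
* upstream (target) inference: ``Sensitivity = sum(I*FC)/sum|FC|`` (a true
  positive rate: +1 when the candidate drives every changed element in its
  observed direction, -1 for a perfect counter-regulator) and
  ``Specificity = mean(1 - |I|)`` over unchanged elements (a true negative
  rate).  The upstream ES replaces the fixed baseline with the fold-change
  mass of changed elements the candidate does not regulate.

Significance comes from a permutation null: element identities of the
changed list are re-drawn among map elements of the same biological type,
keeping the FC multiset fixed; a zero-centred half-normal is fitted to each
sign direction of the null statistics, and a two-sided p-value is derived
from the direction-matched z-score via a series expansion of the normal
tail, with |z| capped at 14 (p floor ~1.56e-44).  Benjamini-Hochberg FDR is
applied across all enriched elements of a sample before any user filtering.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mim import BioType, MIMGraph

logger = logging.getLogger("twodea.enrich")

__all__ = [
    "DataError",
    "DegenerateNullError",
    "DCESet",
    "NullModel",
    "HalfNormalFit",
    "read_dce_table",
    "data_samples",
    "filter_dces",
    "phenotype_level",
    "normalize_levels",
    "saturation",
    "enrichment_score",
    "sensitivity",
    "specificity",
    "upstream_es",
    "permutation_null",
    "gaussian_half_fit",
    "z_and_p",
    "two_sided_p",
    "bh_adjust",
    "run_downstream",
    "run_upstream",
    "in_silico_perturbation",
    "Z_CUTOFF",
    "P_FLOOR",
]


class DataError(Exception):
    """Malformed or unusable input data."""


class DegenerateNullError(Exception):
    """The permutation null carries no variance in the required direction."""


#: z-score cutoff for the tail series; caps the attainable p-value
Z_CUTOFF = 14.0
#: two-sided p at the cutoff (2 * P(Z > 14))
P_FLOOR = 1.56e-44

_SQRT_2PI = math.sqrt(2.0 * math.pi)


# ----------------------------------------------------------------------
# input data


@dataclasses.dataclass
class DCESet:
    """One sample's differentially changed elements after filtering.

    ``ids`` are map element ids (already symbol-matched), ``fc`` the signed
    log2 fold changes, ``adj_p`` the adjusted p-values they passed the
    filter with.
    """

    sample: str
    ids: list
    fc: np.ndarray
    adj_p: np.ndarray
    filter_spec: tuple = (0.05, 0.0, None)

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        self.adj_p = np.asarray(self.adj_p, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise DataError(f"sample {self.sample!r}: duplicate element ids")

    def __len__(self) -> int:
        return len(self.ids)


def read_dce_table(source: str | Path) -> pd.DataFrame:
    """Read a tab-delimited differential-change table.

    Layout: a symbol column first, then per-sample column pairs
    ``FC_<sample>`` and ``padj_<sample>``.  Lines starting with ``#`` are
    ignored.
    """
    source = Path(source)
    try:
        table = pd.read_csv(source, sep="\t", comment="#", dtype={0: str})
    except Exception as exc:  # pandas raises several parser error types
        raise DataError(f"{source}: cannot parse table ({exc})") from exc
    if table.shape[1] < 3:
        raise DataError(f"{source}: expected symbol + (FC, padj) column pairs")
    symbol_col = table.columns[0]
    table = table.rename(columns={symbol_col: "symbol"})
    for col in table.columns[1:]:
        if not (col.startswith("FC_") or col.startswith("padj_")):
            raise DataError(
                f"{source}: column {col!r} is neither FC_<sample> nor padj_<sample>"
            )
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise DataError(
                f"{source}: non-numeric value in column {col!r} at line {line}"
            )
        table[col] = converted
    fc_samples = {c[3:] for c in table.columns if c.startswith("FC_")}
    padj_samples = {c[5:] for c in table.columns if c.startswith("padj_")}
    if fc_samples != padj_samples:
        odd = sorted(fc_samples ^ padj_samples)
        raise DataError(f"{source}: unpaired FC/padj columns for samples {odd}")
    return table


def data_samples(table: pd.DataFrame) -> list:
    """Sample labels present in a differential-change table (column order)."""
    return [c[3:] for c in table.columns if c.startswith("FC_")]


def filter_dces(
    table: pd.DataFrame,
    sample: str,
    graph: MIMGraph,
    p_threshold: float = 0.05,
    abs_fc_threshold: float = 0.0,
    bio_types: Iterable[BioType] | None = None,
) -> tuple[DCESet, list]:
    """Filter one sample's rows to significant changes matched to the map.

    Keeps rows with ``adj_p < p_threshold`` and ``|FC| > abs_fc_threshold``,
    resolves symbols against the map (exact id first, case-insensitive name
    second) and returns the matched set together with the list of unmatched
    symbols — nothing is dropped silently.
    """
    fc_col, p_col = f"FC_{sample}", f"padj_{sample}"
    for col in (fc_col, p_col):
        if col not in table.columns:
            raise DataError(f"sample {sample!r} not present in data table")
    allowed = frozenset(bio_types) if bio_types is not None else None

    ids: list = []
    fc: list = []
    adj_p: list = []
    unmatched: list = []
    seen: set = set()
    for row in table.itertuples(index=False):
        symbol = getattr(row, "symbol")
        value = getattr(row, fc_col)
        pval = getattr(row, p_col)
        if pd.isna(value) or pd.isna(pval):
            continue
        if not (pval < p_threshold and abs(value) > abs_fc_threshold):
            continue
        eid = graph.match_symbol(str(symbol))
        if eid is None:
            unmatched.append(str(symbol))
            continue
        if allowed is not None and graph.element(eid).bio_type not in allowed:
            unmatched.append(str(symbol))
            continue
        if eid in seen:
            logger.warning("sample %s: duplicate element %s kept once", sample, eid)
            continue
        seen.add(eid)
        ids.append(eid)
        fc.append(float(value))
        adj_p.append(float(pval))
    if unmatched:
        logger.info(
            "sample %s: %d symbols not matched to the map", sample, len(unmatched)
        )
    dce = DCESet(
        sample=sample,
        ids=ids,
        fc=np.array(fc, dtype=float),
        adj_p=np.array(adj_p, dtype=float),
        filter_spec=(p_threshold, abs_fc_threshold, allowed),
    )
    return dce, unmatched


# ----------------------------------------------------------------------
# elementary statistics (array-level)


def phenotype_level(influence: np.ndarray, fc: np.ndarray) -> float:
    """Estimated activity change: ``sum I * FC`` (exact sum, unclamped)."""
    influence = np.asarray(influence, float)
    fc = np.asarray(fc, float)
    return float((influence * fc).sum())


def normalize_levels(levels: Mapping[str, Mapping[str, float]]) -> dict:
    """Normalize per-phenotype levels across samples by the absolute
    maximum, preserving sign; an all-zero phenotype stays zero.

    ``levels`` maps phenotype -> {sample: level}; the result has the same
    shape with values in [-1, 1].
    """
    out: dict = {}
    for phenotype, per_sample in levels.items():
        peak = max((abs(x) for x in per_sample.values()), default=0.0)
        if peak == 0.0:
            out[phenotype] = {s: 0.0 for s in per_sample}
        else:
            out[phenotype] = {s: x / peak for s, x in per_sample.items()}
    return out


def saturation(dce_ids: Iterable[str], column: Mapping[str, float]) -> float | None:
    """Influence-weighted fraction of a phenotype's regulators that are
    DCEs: ``sum_{u in DCEs} |I| / sum_{u in V} |I|``; ``None`` when the
    phenotype has no regulators (never 0/0)."""
    total = sum(abs(s) for s in column.values())
    if total == 0.0:
        return None
    dce = set(dce_ids)
    hit = sum(abs(s) for u, s in column.items() if u in dce)
    return hit / total


def enrichment_score(influence: np.ndarray, fc: np.ndarray, k: float = 2.0) -> float:
    """Downstream enrichment score with baseline mass ``k`` (Fig.-style
    regression-through-origin slope); bounded to [-1, 1] for ``k >= 0``."""
    if k < 0:
        raise ValueError("baseline k must be >= 0")
    influence = np.asarray(influence, float)
    fc = np.asarray(fc, float)
    xy = influence * fc
    denom = k + float((xy * xy).sum())
    if denom == 0.0:
        return 0.0
    return float((np.abs(xy) * xy).sum()) / denom


def sensitivity(influence: np.ndarray, fc: np.ndarray) -> float | None:
    """True-positive-rate-like score ``sum(I*FC) / sum|FC|`` over DCEs;
    ``None`` for an empty DCE set."""
    influence = np.asarray(influence, float)
    fc = np.asarray(fc, float)
    denom = float(np.abs(fc).sum())
    if denom == 0.0:
        return None
    return float((influence * fc).sum()) / denom


def specificity(non_dce_influence: np.ndarray) -> float | None:
    """True-negative-rate-like score ``mean(1 - |I|)`` over the non-DCE
    universe; ``None`` when that universe is empty."""
    arr = np.asarray(non_dce_influence, float)
    if arr.size == 0:
        return None
    return float((1.0 - np.abs(arr)).mean())


def upstream_es(
    influence: np.ndarray, fc: np.ndarray, strict_k: bool = False
) -> float:
    """Upstream enrichment score: the fixed baseline is replaced by the
    fold-change mass of DCEs the candidate does not regulate.

    By default that mass is ``sum |FC|`` over unregulated DCEs, keeping the
    denominator positive; ``strict_k=True`` sums the signed FC exactly as
    the formula prints it (the denominator may then vanish, in which case
    the score is reported as 0).
    """
    influence = np.asarray(influence, float)
    fc = np.asarray(fc, float)
    xy = influence * fc
    unregulated = fc[influence == 0.0]
    k_term = float(unregulated.sum()) if strict_k else float(np.abs(unregulated).sum())
    denom = k_term + float((xy * xy).sum())
    if denom == 0.0:
        return 0.0
    return float((np.abs(xy) * xy).sum()) / denom


# ----------------------------------------------------------------------
# normal tail / p-values


def _tail_series(z: float, tol: float = 1e-18) -> float:
    """Upper tail ``P(Z > z)`` by the Maclaurin series of the normal CDF
    integral; accurate for small ``z`` (cancellation grows like
    ``exp(z^2/2)``, so larger ``z`` uses the continued fraction)."""
    total = 0.0
    term = z
    n = 0
    while abs(term) >= tol:
        total += term / (2 * n + 1)
        n += 1
        term *= -z * z / (2 * n)
        if n > 500:  # safety: series always converges well before this
            break
    return 0.5 - total / _SQRT_2PI


def _tail_cf(z: float, depth: int = 80) -> float:
    """Upper tail via the continued-fraction form of the Mills ratio;
    numerically stable for large ``z`` where the series cancels."""
    f = z
    for i in range(depth, 0, -1):
        f = z + i / f
    return math.exp(-0.5 * z * z) / _SQRT_2PI / f


def normal_upper_tail(z: float) -> float:
    if z < 0:
        return 1.0 - normal_upper_tail(-z)
    return _tail_series(z) if z <= 4.0 else _tail_cf(z)


def two_sided_p(z: float) -> float:
    """Two-sided normal p-value ``2 * P(Z > |z|)`` with ``|z|`` capped at
    :data:`Z_CUTOFF`, flooring p at ~1.56e-44."""
    az = min(abs(z), Z_CUTOFF)
    return min(1.0, 2.0 * normal_upper_tail(az))


@dataclasses.dataclass
class HalfNormalFit:
    """Zero-centred half-normal scales fitted per sign direction."""

    sigma_pos: float | None
    sigma_neg: float | None
    pos_fallback: bool = False
    neg_fallback: bool = False
    n_pos: int = 0
    n_neg: int = 0

    def sigma_for(self, stat: float) -> float:
        sigma = self.sigma_pos if stat >= 0 else self.sigma_neg
        if sigma is None or sigma <= 0.0:
            raise DegenerateNullError(
                "null distribution degenerate in the required direction"
            )
        return sigma


def gaussian_half_fit(samples: np.ndarray) -> HalfNormalFit:
    """Fit a separate zero-centred half-normal to each sign direction of
    the null statistics (method of moments: ``sigma^2`` = mean of squared
    same-signed values).  A direction with fewer than two values falls back
    to the other direction's scale and is flagged."""
    arr = np.asarray(samples, float)
    if arr.size == 0:
        raise DegenerateNullError("empty null sample")
    pos = arr[arr > 0]
    neg = arr[arr < 0]
    sigma_pos = float(np.sqrt((pos * pos).mean())) if pos.size >= 2 else None
    sigma_neg = float(np.sqrt((neg * neg).mean())) if neg.size >= 2 else None
    pos_fb = neg_fb = False
    if sigma_pos is None and sigma_neg is not None:
        sigma_pos, pos_fb = sigma_neg, True
        logger.info("positive half-fit fell back to the negative direction")
    if sigma_neg is None and sigma_pos is not None and not pos_fb:
        sigma_neg, neg_fb = sigma_pos, True
        logger.info("negative half-fit fell back to the positive direction")
    if sigma_pos is None and sigma_neg is None:
        raise DegenerateNullError("null distribution is identically zero")
    return HalfNormalFit(sigma_pos, sigma_neg, pos_fb, neg_fb, pos.size, neg.size)


def z_and_p(stat: float, fit: HalfNormalFit) -> tuple[float, float]:
    """Direction-matched z-score (mean 0, half-normal scale) and two-sided
    p-value, with |z| capped at :data:`Z_CUTOFF`."""
    sigma = fit.sigma_for(stat)
    z = stat / sigma
    z = math.copysign(min(abs(z), Z_CUTOFF), z)
    return z, two_sided_p(z)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaNs pass through."""
    arr = np.asarray(p_values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
# permutation null


@dataclasses.dataclass
class NullModel:
    """A permutation null: ``n`` randomized statistic values plus the
    per-direction half-normal fits."""

    n: int
    seed: int
    samples: np.ndarray
    fit: HalfNormalFit | None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)


def _element_index(graph: MIMGraph) -> tuple[list, dict]:
    ids = graph.element_ids()
    return ids, {eid: i for i, eid in enumerate(ids)}


def _permutation_indices(
    graph: MIMGraph,
    dce: DCESet,
    n: int,
    rng: np.random.Generator,
    id_index: dict,
) -> np.ndarray:
    """Draw ``n`` randomized identity lists: each DCE slot is re-assigned to
    a distinct map element of the same biological type, keeping the FC
    values in place (the FC multiset is preserved exactly)."""
    m = len(dce.ids)
    idx = np.empty((n, m), dtype=np.intp)
    slots_by_type: dict[BioType, list] = defaultdict(list)
    for pos, eid in enumerate(dce.ids):
        slots_by_type[graph.element(eid).bio_type].append(pos)
    for bio_type, positions in sorted(slots_by_type.items(), key=lambda kv: kv[0].value):
        pool = np.array(
            [id_index[e] for e in graph.elements_of_type(bio_type)], dtype=np.intp
        )
        c = len(positions)
        if c > pool.size:
            raise DataError(
                f"cannot randomize {c} elements among {pool.size} map elements "
                f"of type {bio_type.value!r}"
            )
        order = np.argsort(rng.random((n, pool.size)), axis=1)[:, :c]
        idx[:, positions] = pool[order]
    return idx


def permutation_null(
    graph: MIMGraph,
    dces: DCESet,
    statistic: Callable[[list, np.ndarray], float],
    n: int = 1000,
    seed: int = 0,
) -> NullModel:
    """Generic permutation null for an arbitrary statistic.

    ``statistic(ids, fc)`` receives each randomized identity list together
    with the (fixed) FC vector.  Reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(seed)
    element_ids, id_index = _element_index(graph)
    idx = _permutation_indices(graph, dces, n, rng, id_index)
    samples = np.array(
        [statistic([element_ids[j] for j in row], dces.fc) for row in idx]
    )
    try:
        fit = gaussian_half_fit(samples)
    except DegenerateNullError:
        fit = None
    return NullModel(n=n, seed=seed, samples=samples, fit=fit)


# ----------------------------------------------------------------------
# batch drivers


def _dense_vector(values: Mapping[str, float], id_index: dict) -> np.ndarray:
    dense = np.zeros(len(id_index))
    for eid, score in values.items():
        pos = id_index.get(eid)
        if pos is not None:
            dense[pos] = score
    return dense


def _es_rows(I: np.ndarray, fc: np.ndarray, k: float) -> np.ndarray:
    xy = I * fc
    denom = k + (xy * xy).sum(axis=1)
    num = (np.abs(xy) * xy).sum(axis=1)
    return np.divide(num, denom, out=np.zeros_like(num), where=denom != 0)


def _safe_zp(stat: float, samples: np.ndarray) -> tuple[float, float]:
    try:
        return z_and_p(stat, gaussian_half_fit(samples))
    except DegenerateNullError:
        return float("nan"), float("nan")


STATISTIC_MODES = ("es", "level", "max_p", "min_p")
K_MODES = ("fixed", "adaptive")


def run_downstream(
    graph: MIMGraph,
    influence,
    dce_sets: Sequence[DCESet],
    statistic_mode: str = "es",
    n: int = 1000,
    seed: int = 0,
    k: float = 2.0,
    k_mode: str = "fixed",
) -> pd.DataFrame:
    """Downstream (phenotype) enrichment over one or more samples.

    Returns one row per influence-table target per sample with the level
    (raw and cross-sample normalized), saturation, ES, direction-matched
    z-scores and p-values for both the ES and Level statistics, the p
    selected by ``statistic_mode`` (``es``, ``level``, ``max_p`` or
    ``min_p``) and its BH-adjusted value (adjusted within each sample over
    all targets, before any user filtering).

    With ``k_mode="adaptive"`` the ES baseline is set to the largest |FC|
    of the sample's DCE list; permutations keep the FC multiset, so the
    observed and randomized scores share the same baseline.
    """
    if statistic_mode not in STATISTIC_MODES:
        raise ValueError(f"unknown statistic_mode {statistic_mode!r}")
    if k_mode not in K_MODES:
        raise ValueError(f"unknown k_mode {k_mode!r}")
    rng = np.random.default_rng(seed)
    element_ids, id_index = _element_index(graph)
    targets = influence.targets()

    rows: list[dict] = []
    levels: dict[str, dict[str, float]] = defaultdict(dict)
    for dce in dce_sets:
        m = len(dce)
        k_eff = k if (k_mode == "fixed" or m == 0) else float(np.abs(dce.fc).max())
        dce_pos = np.array([id_index[e] for e in dce.ids], dtype=np.intp)
        idx = (
            _permutation_indices(graph, dce, n, rng, id_index) if m else None
        )
        for v in targets:
            column = influence.column(v)
            dense = _dense_vector(column, id_index)
            i_obs = dense[dce_pos] if m else np.empty(0)
            level = phenotype_level(i_obs, dce.fc)
            sat = saturation(dce.ids, column)
            es = enrichment_score(i_obs, dce.fc, k_eff)
            if idx is not None:
                I = dense[idx]
                xy = I * dce.fc
                es_r = _es_rows(I, dce.fc, k_eff)
                level_r = xy.sum(axis=1)
                z_es, p_es = _safe_zp(es, es_r)
                z_level, p_level = _safe_zp(level, level_r)
            else:
                z_es = p_es = z_level = p_level = float("nan")
            if statistic_mode == "es":
                z_sel, p_sel = z_es, p_es
            elif statistic_mode == "level":
                z_sel, p_sel = z_level, p_level
            elif statistic_mode == "max_p":
                z_sel, p_sel = (
                    (z_es, p_es) if not (p_es < p_level) else (z_level, p_level)
                )
            else:  # min_p
                z_sel, p_sel = (
                    (z_es, p_es) if not (p_es > p_level) else (z_level, p_level)
                )
            levels[v][dce.sample] = level
            rows.append(
                {
                    "sample": dce.sample,
                    "element": v,
                    "n_dces": m,
                    "level": level,
                    "saturation": sat,
                    "es": es,
                    "k": k_eff,
                    "z_es": z_es,
                    "p_es": p_es,
                    "z_level": z_level,
                    "p_level": p_level,
                    "z": z_sel,
                    "p": p_sel,
                    "statistic_mode": statistic_mode,
                    "n_permutations": n,
                    "seed": seed,
                }
            )

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    norm = normalize_levels(levels)
    result["level_norm"] = [
        norm[row.element][row.sample] for row in result.itertuples(index=False)
    ]
    result["adj_p"] = np.nan
    for sample in result["sample"].unique():
        mask = result["sample"] == sample
        result.loc[mask, "adj_p"] = bh_adjust(result.loc[mask, "p"].to_numpy())
    return result


def run_upstream(
    graph: MIMGraph,
    influence,
    dce_sets: Sequence[DCESet],
    target_types: Iterable[BioType] | None = None,
    n: int = 1000,
    seed: int = 0,
    strict_k: bool = False,
    universe_types: Iterable[BioType] | None = None,
) -> pd.DataFrame:
    """Upstream (target) enrichment: rank candidate regulators of the data.

    Candidates are every element with at least one outgoing influence entry
    in ``influence`` (an upstream-context table, e.g. transcriptional).
    Sensitivity/specificity, the adapted ES and its permutation p-value are
    computed per candidate and sample; BH adjustment runs over *all*
    candidates of a sample, and the ``target_types`` filter is applied only
    afterwards.  Output is ranked by |sensitivity| desc, then specificity
    desc, then id.

    ``universe_types`` sets the specificity universe (and the permutation
    strata fall out of the DCE types themselves); it defaults to the
    biological types present among the matched DCEs.
    """
    rng = np.random.default_rng(seed)
    element_ids, id_index = _element_index(graph)
    candidates = influence.sources()

    rows: list[dict] = []
    for dce in dce_sets:
        m = len(dce)
        if m == 0:
            logger.warning("sample %s has no DCEs; upstream results missing", dce.sample)
        if universe_types is None:
            u_types = sorted(
                {graph.element(e).bio_type for e in dce.ids}, key=lambda t: t.value
            )
        else:
            u_types = sorted(set(universe_types), key=lambda t: t.value)
        universe = [e for t in u_types for e in graph.elements_of_type(t)]
        dce_set = set(dce.ids)
        non_dce_pos = np.array(
            [id_index[e] for e in universe if e not in dce_set], dtype=np.intp
        )
        dce_pos = np.array([id_index[e] for e in dce.ids], dtype=np.intp)
        idx = _permutation_indices(graph, dce, n, rng, id_index) if m else None

        for v in candidates:
            dense = _dense_vector(influence.row(v), id_index)
            i_obs = dense[dce_pos] if m else np.empty(0)
            sens = sensitivity(i_obs, dce.fc) if m else None
            spec = specificity(dense[non_dce_pos]) if non_dce_pos.size else None
            es = upstream_es(i_obs, dce.fc, strict_k) if m else float("nan")
            if idx is not None:
                I = dense[idx]
                xy = I * dce.fc
                k_source = dce.fc if strict_k else np.abs(dce.fc)
                k_term = np.where(I == 0.0, k_source, 0.0).sum(axis=1)
                denom = k_term + (xy * xy).sum(axis=1)
                num = (np.abs(xy) * xy).sum(axis=1)
                es_r = np.divide(num, denom, out=np.zeros_like(num), where=denom != 0)
                z, p = _safe_zp(es, es_r)
            else:
                z = p = float("nan")
            rows.append(
                {
                    "sample": dce.sample,
                    "element": v,
                    "bio_type": graph.element(v).bio_type.value,
                    "n_dces": m,
                    "sensitivity": sens,
                    "specificity": spec,
                    "es": es,
                    "z": z,
                    "p": p,
                    "n_permutations": n,
                    "seed": seed,
                }
            )

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["adj_p"] = np.nan
    for sample in result["sample"].unique():
        mask = result["sample"] == sample
        result.loc[mask, "adj_p"] = bh_adjust(result.loc[mask, "p"].to_numpy())

    # user-level type filtering happens only after FDR correction
    if target_types is not None:
        allowed = {t.value for t in target_types}
        result = result[result["bio_type"].isin(allowed)].copy()

    result["_sens_mag"] = result["sensitivity"].abs().fillna(-1.0)
    result["_spec"] = result["specificity"].fillna(-1.0)
    result = result.sort_values(
        ["sample", "_sens_mag", "_spec", "element"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).drop(columns=["_sens_mag", "_spec"])
    result["rank"] = result.groupby("sample").cumcount() + 1
    return result.reset_index(drop=True)


def in_silico_perturbation(
    graph: MIMGraph,
    influence,
    perturbations: Sequence[tuple],
) -> pd.DataFrame:
    """Data-independent exploration: assume fold changes for a handful of
    elements (typically +1/-1) and report the resulting phenotype levels.
    No statistics are computed — this mirrors the exploratory workflow where
    a user perturbs map elements by hand."""
    ids = []
    fcs = []
    for eid, fc in perturbations:
        if eid not in graph:
            raise DataError(f"perturbed element {eid!r} not in map")
        ids.append(eid)
        fcs.append(float(fc))
    fc_arr = np.array(fcs)
    rows = []
    for v in influence.targets():
        column = influence.column(v)
        i_vec = np.array([column.get(e, 0.0) for e in ids])
        rows.append({"element": v, "level": phenotype_level(i_vec, fc_arr)})
    return pd.DataFrame(rows)
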