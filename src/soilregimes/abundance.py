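"""Absolute abundance, replicate noise model, enrichment calls, and NMF.

Count tables carry ASV x sample integer counts together with the summed
counts of two internal-standard (spike-in) taxa added at known, equal
amounts before DNA extraction.  Dividing by the spike-in counts converts
compositional read counts into absolute abundances.

Replicate-to-replicate scatter of counts is described by a two-component
Gaussian noise model: an ASV with mean abundance ``n`` counts has standard
deviation

    sigma(n) = sqrt((c_frac * n)^2 + c0^2),

with the fractional part ``c_frac`` calibrated on moderate-abundance ASVs
(> 50 counts) and the constant floor ``c0`` calibrated by a coverage
criterion on all replicate comparisons.  Enrichment of an ASV in the
growth-permissive (CHL-) arm relative to the growth-arrested (CHL+) arm is
scored as a z-score per replicate pair under this noise model; the median z
across pairs is compared with a Bonferroni-corrected critical value.

Phylum-level log growth folds across conditions form a non-negative matrix
G which a rank-2 non-negative matrix factorization (multiplicative updates)
decomposes into two growth modes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CountTable",
    "NoiseModel",
    "NMFResult",
    "normalize_spike_in",
    "total_biomass",
    "estimate_noise_model",
    "critical_z",
    "enrichment_zscores",
    "aggregate_enriched",
    "phylum_abundance",
    "growth_fold_matrix",
    "nmf_rank2",
    "survival_folds",
    "PSEUDOCOUNT",
    "PSEUDO_ABUNDANCE",
]

#: Pseudocount added to raw ASV counts before spike-in division.
PSEUDOCOUNT = 0.5
#: Pseudo-abundance added inside the growth/survival-fold logarithms.
PSEUDO_ABUNDANCE = 1e-3


@dataclass
class CountTable:
    """ASV x sample counts with spike-in reference, taxonomy and metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, index = ASV ids, columns = sample ids.
        The spike-in ASVs must already be removed from this table.
    spike_in : Series
        Per-sample summed spike-in counts (> 0 for retained samples).
    taxonomy : Series or DataFrame
        ASV -> phylum map (Series), or a DataFrame with a ``phylum`` column
        and optionally finer ranks.
    meta : DataFrame
        Per-sample metadata indexed by sample id; conventional columns are
        soil_id, perturbed_pH, replicate, chl, timepoint, nitrate.
    """

    counts: pd.DataFrame
    spike_in: pd.Series
    taxonomy: Optional[pd.DataFrame] = None
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if isinstance(self.taxonomy, pd.Series):
            self.taxonomy = self.taxonomy.to_frame(name="phylum")
        self.spike_in = self.spike_in.reindex(self.counts.columns)
        bad = self.spike_in.isna() | (self.spike_in <= 0)
        if bad.any():
            dropped = list(self.spike_in.index[bad])
            warnings.warn(
                f"dropping {len(dropped)} sample(s) with zero/missing spike-in "
                f"counts: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
            keep = self.counts.columns[~bad.to_numpy()]
            self.counts = self.counts[keep]
            self.spike_in = self.spike_in[keep]
        if self.meta is not None:
            self.meta = self.meta.reindex(self.counts.columns)

    def phylum_of(self, asv: str) -> str:
        if self.taxonomy is None or asv not in self.taxonomy.index:
            return "unassigned"
        ph = self.taxonomy.loc[asv, "phylum"]
        return "unassigned" if pd.isna(ph) else str(ph)

    def select(self, mask: pd.Series) -> "CountTable":
        """Subset samples by a boolean mask over the metadata."""
        cols = self.meta.index[mask.to_numpy(dtype=bool)]
        return CountTable(
            counts=self.counts[cols],
            spike_in=self.spike_in[cols],
            taxonomy=self.taxonomy,
            meta=self.meta.loc[cols],
        )


def normalize_spike_in(table: CountTable, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Absolute abundances: (count + pseudocount) / spike-in, per ASV and sample."""
    return (table.counts + pseudocount).div(table.spike_in, axis=1)


def total_biomass(table: CountTable) -> pd.Series:
    """Total analyte reads over spike-in reads per sample (no pseudocount)."""
    return table.counts.sum(axis=0) / table.spike_in


@dataclass(frozen=True)
class NoiseModel:
    """Two-component replicate noise model sigma(n) = sqrt((c_frac n)^2 + c0^2)."""

    c_frac: float
    c0: float
    coverage_rule: str = "difference"
    scope: str = ""

    def __post_init__(self) -> None:
        if self.c_frac < 0 or self.c0 < 0:
            raise ValueError("noise parameters must be non-negative")

    def sigma(self, n: np.ndarray) -> np.ndarray:
        """Per-measurement standard deviation at mean abundance n counts."""
        n = np.asarray(n, dtype=float)
        return np.sqrt((self.c_frac * n) ** 2 + self.c0**2)


_MIN_MEAN_FOR_CFRAC = 50.0


def _replicate_pairs(counts: pd.DataFrame) -> Iterable[Tuple[np.ndarray, np.ndarray]]:
    cols = list(counts.columns)
    for i, j in itertools.combinations(range(len(cols)), 2):
        yield counts.iloc[:, i].to_numpy(float), counts.iloc[:, j].to_numpy(float)


#: Coverage of a +/- 1 sigma band under a Gaussian; the calibration's "67%".
ONE_SIGMA_COVERAGE = 0.6827


def estimate_noise_model(
    replicate_counts: pd.DataFrame,
    coverage: float = ONE_SIGMA_COVERAGE,
    coverage_rule: str = "difference",
    min_mean: float = _MIN_MEAN_FOR_CFRAC,
    continuity_correction: float = 0.5,
    scope: str = "",
) -> NoiseModel:
    """Calibrate (c_frac, c0) from a set of replicate count columns.

    ``replicate_counts`` holds the ASV counts of >= 2 biological replicates
    of one condition (one soil x perturbed pH; the model is calibrated
    per condition because samples were processed in separate runs).

    c_frac is a robust Gaussian scale of replicate-pair differences among
    ASVs with pair mean > ``min_mean`` counts, where the constant floor is
    negligible: 1.4826 * median(|n_i - n_j| / n_mean) / sqrt(2) (the sqrt(2)
    converts a difference of two noisy measurements to a per-measurement
    scale).

    c0 is then the smallest value for which a fraction ``coverage`` of all
    replicate comparisons falls inside a one-sigma band, found by bisection.
    With ``coverage_rule="difference"`` (default) the band is the one-sigma
    spread of a replicate difference, sqrt(2)*sigma(c0, c_frac, n_mean);
    ``"literal"`` uses sigma itself as the band (in which case c0 absorbs
    the sqrt(2) and ceases to estimate the per-measurement floor).  The
    default coverage is the exact Gaussian one-sigma mass 0.6827; integer
    counts are compared to the continuous band with a half-count continuity
    correction so the calibration stays unbiased at small abundances.
    """
    if isinstance(replicate_counts, pd.DataFrame):
        groups: List[pd.DataFrame] = [replicate_counts]
    else:  # a sequence of replicate sets (e.g. the CHL- and CHL+ triplets)
        groups = list(replicate_counts)
    if all(g.shape[1] < 2 for g in groups):
        raise ValueError("need at least 2 replicates to estimate noise")
    if coverage_rule not in ("difference", "literal"):
        raise ValueError(f"unknown coverage_rule {coverage_rule!r}")

    ratios: List[np.ndarray] = []
    diffs: List[np.ndarray] = []
    means: List[np.ndarray] = []
    for a, b in itertools.chain.from_iterable(_replicate_pairs(g) for g in groups):
        nbar = 0.5 * (a + b)
        d = np.abs(a - b)
        hi = nbar > min_mean
        if hi.any():
            ratios.append(d[hi] / nbar[hi])
        nz = nbar > 0
        diffs.append(d[nz])
        means.append(nbar[nz])
    if not ratios:
        raise ValueError(
            f"no ASVs with pair mean > {min_mean} counts in scope {scope!r}; "
            "c_frac is inestimable"
        )
    c_frac = float(1.4826 * np.median(np.concatenate(ratios)) / math.sqrt(2))
    d = np.concatenate(diffs)
    n = np.concatenate(means)

    band_factor = math.sqrt(2) if coverage_rule == "difference" else 1.0

    d_corr = np.where(d > 0, d + continuity_correction, 0.0)

    def frac_within(c0: float) -> float:
        band = band_factor * np.sqrt((c_frac * n) ** 2 + c0**2)
        return float(np.mean(d_corr <= band))

    if frac_within(0.0) >= coverage:
        c0 = 0.0
    else:
        lo, hi = 0.0, float(max(d.max(), 1.0))
        while frac_within(hi) < coverage:
            hi *= 2.0
            if hi > 1e9:  # pragma: no cover - pathological inputs
                break
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if frac_within(mid) >= coverage:
                hi = mid
            else:
                lo = mid
        c0 = hi
    return NoiseModel(c_frac=c_frac, c0=float(c0), coverage_rule=coverage_rule, scope=scope)


def critical_z(alpha: float = 0.05, n_asv: int = 1) -> float:
    """Bonferroni-corrected two-tailed critical z: Phi^-1(1 - alpha/2/n_asv)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_asv < 1:
        raise ValueError("n_asv must be >= 1")
    return float(norm.ppf(1.0 - alpha / 2.0 / n_asv))


def enrichment_zscores(
    counts_minus: pd.DataFrame,
    counts_plus: pd.DataFrame,
    noise: NoiseModel,
    alpha: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
    n_asv: Optional[int] = None,
) -> pd.DataFrame:
    """Per-ASV enrichment of CHL- endpoint counts over the CHL+ control.

    Columns of ``counts_minus``/``counts_plus`` are replicates; replicate i
    of one arm pairs with replicate i of the other (by column order).  For
    each pair, z = (c- - c+) / sqrt(sigma^2(c-) + sigma^2(c+)) on the
    (pseudocounted) count scale.  The median z over pairs is compared with
    critical_z(alpha, n_asv), where n_asv defaults to the number of ASVs
    with a nonzero count in any of the compared samples.

    Returns a DataFrame indexed by ASV with per-pair z columns, median_z,
    and an ``enriched`` flag.
    """
    counts_minus, counts_plus = counts_minus.align(counts_plus, axis=0)
    counts_minus = counts_minus.fillna(0.0)
    counts_plus = counts_plus.fillna(0.0)
    n_minus, n_plus = counts_minus.shape[1], counts_plus.shape[1]
    n_pairs = min(n_minus, n_plus)
    if n_minus != n_plus:
        warnings.warn(
            f"unequal replicate counts ({n_minus} CHL- vs {n_plus} CHL+); "
            f"pairing the first {n_pairs} by sorted order",
            stacklevel=2,
        )
    if n_pairs == 0:
        raise ValueError("no replicate pairs available")

    zcols = {}
    any_nonzero = np.zeros(len(counts_minus), dtype=bool)
    for k in range(n_pairs):
        cm = counts_minus.iloc[:, k].to_numpy(float)
        cp = counts_plus.iloc[:, k].to_numpy(float)
        any_nonzero |= (cm > 0) | (cp > 0)
        cm_p, cp_p = cm + pseudocount, cp + pseudocount
        denom = np.sqrt(noise.sigma(cm_p) ** 2 + noise.sigma(cp_p) ** 2)
        zcols[f"z_pair{k + 1}"] = (cm_p - cp_p) / denom
    out = pd.DataFrame(zcols, index=counts_minus.index)
    out["median_z"] = out.median(axis=1)
    if n_asv is None:
        n_asv = int(any_nonzero.sum())
    zc = critical_z(alpha, max(n_asv, 1))
    out["n_asv"] = n_asv
    out["critical_z"] = zc
    out["enriched"] = out["median_z"] > zc
    return out


def aggregate_enriched(
    per_condition_enriched: Sequence[Set[str]],
    nn_responders: Optional[Set[str]] = None,
) -> Set[str]:
    """Union of enriched ASVs across conditions, minus no-nitrate responders.

    ASVs that also respond in the no-nitrate control are treated as
    false-positive nitrate reducers and removed from the aggregated set.
    """
    union: Set[str] = set()
    for s in per_condition_enriched:
        union |= set(s)
    if nn_responders:
        union -= set(nn_responders)
    return union


def phylum_abundance(
    abundances: pd.DataFrame, taxonomy: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Sum ASV absolute abundances within each phylum (missing -> 'unassigned')."""
    if isinstance(taxonomy, pd.DataFrame):
        taxonomy = taxonomy["phylum"]
    phyla = taxonomy.reindex(abundances.index).fillna("unassigned")
    return abundances.groupby(phyla.to_numpy()).sum()


def growth_fold_matrix(
    abs_minus: pd.DataFrame,
    abs_plus: pd.DataFrame,
    pseudo: float = PSEUDO_ABUNDANCE,
    log=np.log,
) -> pd.DataFrame:
    """Log growth folds g_ij = log(Abs-_ij + 1e-3) - log(Abs+_ij + 1e-3), clipped at 0.

    Rows are phyla, columns are conditions; ``abs_minus`` and ``abs_plus``
    are the phylum-aggregated absolute abundances of the growth-permissive
    and growth-arrested arms.  The CHL+ arm is the reference so that
    abundance effects unrelated to growth cancel; negative entries are set
    to 0 because only growth is of interest.  Natural log by default.
    """
    am, ap = abs_minus.align(abs_plus)
    am = am.fillna(0.0)
    ap = ap.fillna(0.0)
    g = log(am + pseudo) - log(ap + pseudo)
    return g.clip(lower=0.0)


@dataclass
class NMFResult:
    W: pd.DataFrame  # phyla x rank weights
    H: pd.DataFrame  # rank x conditions modes
    variance_explained: float
    objective_history: np.ndarray  # Frobenius error of the best restart
    seed: int


def _nmf_mu(
    G: np.ndarray, rank: int, rng: np.random.Generator, max_iter: int, tol: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF for the Frobenius objective."""
    m, n = G.shape
    scale = math.sqrt(G.mean() / rank) if G.mean() > 0 else 1.0
    W = scale * rng.random((m, rank)) + 1e-6
    H = scale * rng.random((rank, n)) + 1e-6
    eps = 1e-12
    hist = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ G) / (W.T @ W @ H + eps)
        W *= (G @ H.T) / (W @ H @ H.T + eps)
        err = float(np.linalg.norm(G - W @ H, "fro"))
        hist.append(err)
        if prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return W, H, np.asarray(hist)


def nmf_rank2(
    G: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-9,
    rank: int = 2,
) -> NMFResult:
    """Rank-2 NMF of the growth matrix by Frobenius multiplicative updates.

    Runs ``n_restarts`` seeded random initializations and keeps the lowest
    reconstruction error.  variance_explained = 1 - ||G - WH||_F^2 / ||G||_F^2.
    Deterministic given ``seed``.
    """
    Gv = G.to_numpy(dtype=float) if isinstance(G, pd.DataFrame) else np.asarray(G, float)
    if (Gv < 0).any():
        raise ValueError("growth matrix must be non-negative")
    norm_g = np.linalg.norm(Gv, "fro")
    if norm_g == 0:
        raise ValueError("growth matrix is identically zero")
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None
    best_err = np.inf
    for _ in range(n_restarts):
        W, H, hist = _nmf_mu(Gv, rank, rng, max_iter, tol)
        if hist[-1] < best_err:
            best_err = hist[-1]
            best = (W, H, hist)
    W, H, hist = best
    ve = 1.0 - (best_err / norm_g) ** 2
    if isinstance(G, pd.DataFrame):
        widx, hcols = G.index, G.columns
    else:
        widx = pd.RangeIndex(Gv.shape[0])
        hcols = pd.RangeIndex(Gv.shape[1])
    mode_names = [f"mode{k + 1}" for k in range(rank)]
    return NMFResult(
        W=pd.DataFrame(W, index=widx, columns=mode_names),
        H=pd.DataFrame(H, index=mode_names, columns=hcols),
        variance_explained=float(ve),
        objective_history=hist,
        seed=seed,
    )


def survival_folds(
    abs_plus_end: pd.DataFrame | pd.Series,
    abs_t0: pd.DataFrame | pd.Series,
    pseudo: float = PSEUDO_ABUNDANCE,
):
    """Per-phylum survival fold: endpoint CHL+ abundance over T0 abundance.

    A proxy for death in the absence of growth; 1 means no net change.
    The same pseudo-abundance as the growth folds regularizes zeros.
    """
    if isinstance(abs_plus_end, pd.DataFrame) and isinstance(abs_t0, pd.Series):
        return abs_plus_end.add(pseudo).div(abs_t0 + pseudo, axis=0)
    ap, a0 = abs_plus_end.align(abs_t0)
    return (ap.fillna(0.0) + pseudo) / (a0.fillna(0.0) + pseudo)
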