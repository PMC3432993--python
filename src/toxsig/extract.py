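"""Co-expression pattern extraction and gene categorization.

The extraction proceeds in four steps over a preprocessed genes × columns
log2-ratio matrix:

1. per-gene signal/noise/SNR statistics gate candidate genes
   (|S| > s_magnitude, |SNR| > snr_min);
2. candidates are ranked by |SNR| and greedily seeded into patterns: a
   candidate whose correlation local cluster (all genes with Pearson r to it
   at or above the p-threshold radius r*) contains at least
   ``min_cluster_size`` uncovered genes founds a pattern whose representative
   profile is the member mean;
3. patterns whose representatives correlate at or above ``merge_r`` are
   pooled, and one reassignment pass re-derives memberships against the
   final representatives; representatives failing the gates are dropped;
4. every gene is categorized to its best-correlated pattern if it passes all
   three gates: correlation r ≥ r_categorize, magnitude |S| > s_magnitude,
   and |SNR| > snr_min.

The SNR carries the sign of the signal, so magnitude gates use absolute
values throughout — down-regulated patterns are first-class citizens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .groups import VEHICLE_CLASS, GroupStructure
from .stats import ProfileStats, correlation_cutoff, profile_stats, signal

__all__ = [
    "ExtractionParams",
    "Pattern",
    "EPIGExtractor",
    "local_clusters",
    "extract_patterns",
    "categorize_genes",
    "flag_coregulated",
]


@dataclass(frozen=True)
class ExtractionParams:
    """Thresholds of the extraction and categorization gates.

    p_threshold : two-tailed significance of a pairwise Pearson correlation,
        translated to the radius r* of a local cluster.
    r_categorize : correlation gate for assigning a gene to a pattern.
    s_magnitude : minimum |signal| in log2 units.
    snr_min : minimum |SNR| (unitless).
    min_cluster_size : smallest uncovered local cluster that may seed a pattern.
    merge_r : representative-correlation radius for pooling patterns
        (None → same as r*).
    agreement_r : minimum correlation of the two tissues' dose-class mean
        vectors for a pattern to count as cross-tissue co-regulated.
    strict_eq1_sign : literal reading of the signal's all-positive branch.
    """

    p_threshold: float = 0.001
    r_categorize: float = 0.64
    s_magnitude: float = 0.4
    snr_min: float = 3.0
    min_cluster_size: int = 10
    merge_r: float | None = None
    agreement_r: float = 0.5
    strict_eq1_sign: bool = False

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 < self.r_categorize < 1:
            raise ValueError("r_categorize must be in (0, 1)")
        if self.s_magnitude <= 0 or self.snr_min <= 0:
            raise ValueError("s_magnitude and snr_min must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Pattern:
    """An extracted co-expression pattern."""

    pattern_id: int
    profile: np.ndarray  # representative: mean of member profiles
    member_indices: np.ndarray
    member_r: np.ndarray  # Pearson r of each member to the representative
    S: float
    N: float
    SNR: float
    s_by_tissue: dict = field(default_factory=dict)
    coregulated: bool | None = None

    @property
    def n_members(self) -> int:
        return int(self.member_indices.size)


def _row_corr(X: np.ndarray):
    """All-pairs Pearson correlation of matrix rows.

    Returns (corr, valid) where constant rows are marked invalid and get
    zero correlation to everything (they are excluded from clustering).
    """
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    valid = sd > 0
    Z[valid] /= sd[valid][:, None]
    Z[~valid] = 0.0
    corr = (Z @ Z.T) / X.shape[1]
    np.fill_diagonal(corr, 1.0)
    return corr, valid


def _corr_to_profiles(X: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson r of every gene row to every representative profile."""
    Zx = X - X.mean(axis=1, keepdims=True)
    sx = Zx.std(axis=1)
    sx[sx == 0] = np.inf  # constant genes correlate with nothing
    Zp = profiles - profiles.mean(axis=1, keepdims=True)
    sp = Zp.std(axis=1)
    sp[sp == 0] = np.inf
    return (Zx @ Zp.T) / (X.shape[1] * np.outer(sx, sp))


def local_clusters(X, r_star: float):
    """Per-gene neighbor sets: genes with Pearson r ≥ r_star to the gene.

    Symmetric by construction. Constant-profile genes have undefined
    correlations; they are excluded (empty neighbor set) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("local clustering needs at least 2 genes")
    corr, valid = _row_corr(X)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} constant-profile genes excluded from clustering")
    out = []
    for g in range(X.shape[0]):
        if not valid[g]:
            out.append(np.empty(0, dtype=int))
            continue
        nbr = np.where((corr[g] >= r_star) & valid)[0]
        out.append(nbr[nbr != g])
    return out


class EPIGExtractor(ClusterMixin, BaseEstimator):
    """Greedy SNR-ranked extraction of co-expression patterns.

    A clustering-style estimator over genes: ``fit(X, groups=...)`` with X a
    genes × columns log2-ratio matrix (array or DataFrame) and ``groups`` the
    inter-group structure of the columns. After fitting:

    Attributes
    ----------
    patterns_ : list of :class:`Pattern`
    labels_ : int array, categorized pattern id per gene (−1 unassigned)
    assignments_ : DataFrame with per-gene r, S, N, SNR and assignment
    stats_ : :class:`ProfileStats` of the input genes
    r_star_ : correlation radius implied by ``p_threshold``
    """

    def __init__(
        self,
        p_threshold: float = 0.001,
        r_categorize: float = 0.64,
        s_magnitude: float = 0.4,
        snr_min: float = 3.0,
        min_cluster_size: int = 10,
        merge_r: float | None = None,
        agreement_r: float = 0.5,
        strict_eq1_sign: bool = False,
    ):
        self.p_threshold = p_threshold
        self.r_categorize = r_categorize
        self.s_magnitude = s_magnitude
        self.snr_min = snr_min
        self.min_cluster_size = min_cluster_size
        self.merge_r = merge_r
        self.agreement_r = agreement_r
        self.strict_eq1_sign = strict_eq1_sign

    def _params(self) -> ExtractionParams:
        return ExtractionParams(
            p_threshold=self.p_threshold,
            r_categorize=self.r_categorize,
            s_magnitude=self.s_magnitude,
            snr_min=self.snr_min,
            min_cluster_size=self.min_cluster_size,
            merge_r=self.merge_r,
            agreement_r=self.agreement_r,
            strict_eq1_sign=self.strict_eq1_sign,
        )

    def fit(self, X, y=None, *, groups: GroupStructure):
        params = self._params()
        if isinstance(X, pd.DataFrame):
            gene_ids = X.index.to_numpy()
            M = X.to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            gene_ids = np.arange(M.shape[0])
        if not np.isfinite(M).all():
            raise ValueError("expression matrix must be finite after preprocessing")

        stats = profile_stats(M, groups, strict_sign=params.strict_eq1_sign)
        r_star = correlation_cutoff(params.p_threshold, groups.n_columns)
        merge_r = params.merge_r if params.merge_r is not None else r_star

        corr, valid = _row_corr(M)
        eligible = (
            valid
            & (np.abs(stats.S) > params.s_magnitude)
            & (np.abs(stats.SNR) > params.snr_min)
        )

        profiles, member_sets = self._seed_patterns(
            M, corr, valid, eligible, stats, r_star, params
        )
        profiles, member_sets = self._merge(M, profiles, member_sets, merge_r)
        profiles, member_sets = self._reassign(M, profiles, valid, r_star, groups, params)

        self.gene_ids_ = gene_ids
        self.stats_ = stats
        self.r_star_ = r_star
        self.merge_r_ = merge_r
        self.patterns_ = self._build_patterns(M, profiles, member_sets, groups, params)
        self.assignments_ = categorize_genes(M, self.patterns_, stats, params, gene_ids=gene_ids)
        self.labels_ = self.assignments_["pattern_id"].to_numpy()
        self.n_patterns_ = len(self.patterns_)
        return self

    # -- extraction steps -------------------------------------------------

    def _seed_patterns(self, M, corr, valid, eligible, stats: ProfileStats, r_star, params):
        order = np.argsort(-np.abs(stats.SNR), kind="stable")
        covered = ~valid
        profiles, member_sets = [], []
        for g in order:
            if not eligible[g] or covered[g]:
                continue
            members = np.where((corr[g] >= r_star) & ~covered)[0]
            if members.size < params.min_cluster_size:
                continue
            covered[members] = True
            member_sets.append(members)
            profiles.append(M[members].mean(axis=0))
        return profiles, member_sets

    @staticmethod
    def _merge(M, profiles, member_sets, merge_r):
        """Pool patterns whose representatives correlate ≥ merge_r (transitively)."""
        changed = True
        while changed and len(profiles) > 1:
            changed = False
            P = np.vstack(profiles)
            pc, _ = _row_corr(P)
            np.fill_diagonal(pc, -np.inf)
            i, j = np.unravel_index(np.argmax(pc), pc.shape)
            if pc[i, j] >= merge_r:
                merged = np.union1d(member_sets[i], member_sets[j])
                keep = [k for k in range(len(profiles)) if k not in (i, j)]
                member_sets = [member_sets[k] for k in keep] + [merged]
                profiles = [profiles[k] for k in keep] + [M[merged].mean(axis=0)]
                changed = True
        return profiles, member_sets

    def _reassign(self, M, profiles, valid, r_star, groups, params):
        """One pass: re-derive memberships against final representatives."""
        if not profiles:
            return [], []
        P = np.vstack(profiles)
        R = _corr_to_profiles(M, P)
        best = np.argmax(R, axis=1)
        best_r = R[np.arange(M.shape[0]), best]
        member_of = np.where(valid & (best_r >= r_star), best, -1)
        out_profiles, out_members = [], []
        for k in range(P.shape[0]):
            members = np.where(member_of == k)[0]
            if members.size == 0:
                continue
            prof = M[members].mean(axis=0)
            pstats = profile_stats(prof, groups, strict_sign=params.strict_eq1_sign)
            if abs(pstats.S[0]) > params.s_magnitude and abs(pstats.SNR[0]) > params.snr_min:
                out_profiles.append(prof)
                out_members.append(members)
        return out_profiles, out_members

    def _build_patterns(self, M, profiles, member_sets, groups, params):
        patterns = []
        for k, (prof, members) in enumerate(zip(profiles, member_sets), start=1):
            pstats = profile_stats(prof, groups, strict_sign=params.strict_eq1_sign)
            r = _corr_to_profiles(M[members], prof[None, :])[:, 0]
            patterns.append(
                Pattern(
                    pattern_id=k,
                    profile=prof,
                    member_indices=members,
                    member_r=r,
                    S=float(pstats.S[0]),
                    N=float(pstats.N[0]),
                    SNR=float(pstats.SNR[0]),
                )
            )
        return patterns

    def fit_predict(self, X, y=None, **fit_kwargs):
        return self.fit(X, **fit_kwargs).labels_


def extract_patterns(X, groups: GroupStructure, params: ExtractionParams | None = None):
    """Functional wrapper over :class:`EPIGExtractor`; returns the fitted estimator."""
    params = params or ExtractionParams()
    est = EPIGExtractor(**{k: getattr(params, k) for k in ExtractionParams.__dataclass_fields__})
    return est.fit(X, groups=groups)


def categorize_genes(
    X,
    patterns: list,
    stats: ProfileStats,
    params: ExtractionParams | None = None,
    gene_ids=None,
) -> pd.DataFrame:
    """Assign each gene to its best-correlated pattern, gated three ways.

    A gene is assigned to the argmax-r pattern iff r ≥ r_categorize,
    |S| > s_magnitude and |SNR| > snr_min; ties go to the lower pattern id.
    Returns one row per gene: gene_id, pattern_id (−1 if unassigned), r, S,
    N, SNR, assigned.
    """
    params = params or ExtractionParams()
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if gene_ids is None:
        gene_ids = X.index.to_numpy() if isinstance(X, pd.DataFrame) else np.arange(M.shape[0])
    n = M.shape[0]
    if patterns:
        P = np.vstack([p.profile for p in patterns])
        ids = np.array([p.pattern_id for p in patterns])
        order = np.argsort(ids)  # ties in r resolved toward the lower pattern id
        R = _corr_to_profiles(M, P[order])
        best = np.argmax(R, axis=1)
        best_r = R[np.arange(n), best]
        best_id = ids[order][best]
    else:
        best_r = np.full(n, np.nan)
        best_id = np.full(n, -1)
    passes = (
        (best_r >= params.r_categorize)
        & (np.abs(stats.S) > params.s_magnitude)
        & (np.abs(stats.SNR) > params.snr_min)
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "pattern_id": np.where(passes, best_id, -1),
            "r": best_r,
            "S": stats.S,
            "N": stats.N,
            "SNR": stats.SNR,
            "assigned": passes,
        }
    )


def flag_coregulated(
    pattern: Pattern,
    column_meta: pd.DataFrame,
    s_magnitude: float = 0.4,
    agreement_r: float = 0.5,
    strict_eq1_sign: bool = False,
) -> Pattern:
    """Decide whether a pattern moves the same way in both tissues.

    The representative profile is split by tissue; within each tissue the
    signal is computed over dose-class cells (vehicle excluded). The pattern
    is flagged co-regulated iff both tissue signals exceed ``s_magnitude`` in
    magnitude, share their sign, and the two tissues' dose-class mean vectors
    correlate at least ``agreement_r`` (vacuously satisfied when either
    vector is constant, where the correlation is undefined). Updates and
    returns the pattern.
    """
    meta = column_meta.reset_index(drop=True)
    if len(meta) != pattern.profile.size:
        raise ValueError("column metadata length must match the profile")
    keep = meta["dose_class"] != VEHICLE_CLASS
    meta = meta[keep]
    prof = pattern.profile[keep.to_numpy()]

    tissues = sorted(meta["tissue"].unique())
    if len(tissues) != 2:
        raise ValueError(f"co-regulation needs exactly 2 tissues, got {tissues}")
    sigs, mean_vecs = {}, {}
    classes = sorted(meta["dose_class"].unique())
    dclass = meta["dose_class"].to_numpy()
    tis = meta["tissue"].to_numpy()
    for t in tissues:
        sel = tis == t
        if sel.sum() < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 columns")
        means = np.array([prof[sel & (dclass == c)].mean() for c in classes])
        sigs[t] = float(signal(means[None, :], strict_sign=strict_eq1_sign)[0])
        mean_vecs[t] = means

    a, b = tissues
    big = abs(sigs[a]) > s_magnitude and abs(sigs[b]) > s_magnitude
    same_sign = np.sign(sigs[a]) == np.sign(sigs[b])
    va, vb = mean_vecs[a], mean_vecs[b]
    if np.std(va) == 0 or np.std(vb) == 0:
        agree = True
    else:
        agree = float(np.corrcoef(va, vb)[0, 1]) >= agreement_r
    pattern.s_by_tissue = dict(sigs)
    pattern.coregulated = bool(big and same_sign and agree)
    return pattern
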