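"""Convex-hull coverage analysis between site cohorts.

For an ordered pair of sites (query, hull) and a pair of features
(i, j), the directional coverage is

    cov(i, j) = #{query points inside CH_ij(hull site)} / #{query points}

estimated as the mean over bootstrap replicates in which both cohorts
are resampled with replacement at original size and the hull-forming
sample is denoised with DBSCAN. Per-feature coverage is the median of
cov over all pairs containing the feature; the site-pair coverage is the
arithmetic mean of the per-feature values. Features whose coverage falls
strictly below Q1 - 1.5*IQR of the per-feature distribution are flagged
as low-coverage.

All coordinates are z-scored by the hull-side bootstrap sample before
hull construction and membership testing, so the geometric tolerance is
scale-free.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortTable
from .geometry import (
    MEMBERSHIP_TOL,
    DegenerateHullError,
    build_hull,
    denoise_pair,
    pair_coverage,
)

__all__ = [
    "PairCoverage",
    "FeatureCoverageDistribution",
    "SiteCoverageMatrix",
    "bootstrap_pair_coverage",
    "feature_coverage",
    "flag_low_coverage",
    "coverage_matrix",
    "CoverageAnalysis",
    "CoverageResults",
]

QUANTILE_METHOD = "linear"  # linear interpolation between order statistics
IQR_FACTOR = 1.5

DEFAULT_DBSCAN = {"min_samples": 5, "eps": None, "eps_quantile": 0.9}


@dataclasses.dataclass(frozen=True)
class PairCoverage:
    """Bootstrap-averaged coverage of one site by another's hull, one feature pair."""

    query_site: str
    hull_site: str
    feature_pair: tuple[str, str]
    mean_coverage: float
    sd_coverage: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_coverage <= 1.0:
            raise ValueError(f"mean_coverage out of [0,1]: {self.mean_coverage}")
        if self.sd_coverage < 0:
            raise ValueError("sd_coverage must be non-negative")


@dataclasses.dataclass(frozen=True)
class FeatureCoverageDistribution:
    """Per-feature median coverages for one ordered site pair, with flagging."""

    query_site: str
    hull_site: str
    per_feature: dict
    threshold: float | None
    flagged: frozenset
    skipped_pairs: tuple = ()

    def __post_init__(self) -> None:
        for f, v in self.per_feature.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"per-feature coverage out of [0,1]: {f}={v}")
        if not self.flagged <= set(self.per_feature):
            raise ValueError("flagged features must be a subset of per_feature keys")

    @property
    def mean_coverage(self) -> float:
        """Site-pair coverage: arithmetic mean over surviving features."""
        return float(np.mean(list(self.per_feature.values())))


@dataclasses.dataclass(frozen=True)
class SiteCoverageMatrix:
    """Mean coverage for every ordered (query, hull) site pair; diagonal = 1."""

    sites: tuple
    values: pd.DataFrame  # index = query site, columns = hull site

    def __getitem__(self, pair: tuple[str, str]) -> float:
        query, hull = pair
        return float(self.values.loc[query, hull])


def flag_low_coverage(per_feature: Mapping[str, float]) -> tuple[float, frozenset]:
    """Tukey-style low-coverage threshold and flags.

    threshold = Q1 - 1.5 * (Q3 - Q1) of the per-feature coverage values,
    with quartiles by linear interpolation; flagged features fall
    *strictly* below the threshold. Quartiles need at least 4 values.
    """
    if len(per_feature) < 4:
        raise ValueError(
            f"need at least 4 features for quartile-based flagging, got {len(per_feature)}"
        )
    vals = np.asarray(list(per_feature.values()), dtype=float)
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=QUANTILE_METHOD)
    threshold = float(q1 - IQR_FACTOR * (q3 - q1))
    flagged = frozenset(f for f, v in per_feature.items() if v < threshold)
    return threshold, flagged


def bootstrap_pair_coverage(
    query: CohortTable,
    hull: CohortTable,
    feature_pair: tuple[str, str],
    n_boot: int = 100,
    seed: int = 0,
    denoise: bool = True,
    dbscan_params: Mapping | None = None,
    resample: str = "both",
    tol: float = MEMBERSHIP_TOL,
) -> PairCoverage:
    """Bootstrap estimate of the coverage of ``query`` by ``hull``'s 2D hull.

    Each replicate resamples rows with replacement at original size
    (``resample``: "both", "hull" for hull-side only, or "none"),
    z-scores both samples by the hull sample's statistics, optionally
    denoises the hull-forming sample with DBSCAN, builds the hull, and
    counts the query points inside. Identical seeds give identical
    results. Query points are never denoised: removing query outliers
    would silently inflate coverage.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if resample not in {"both", "hull", "none"}:
        raise ValueError(f"resample must be 'both', 'hull' or 'none', got {resample!r}")
    fi, fj = feature_pair
    for c in (query, hull):
        for f in (fi, fj):
            if f not in c.features:
                raise KeyError(f"feature {f!r} not in site {c.site_id!r}")
    Xq = query.data.loc[:, [fi, fj]].to_numpy(dtype=float)
    Xh = hull.data.loc[:, [fi, fj]].to_numpy(dtype=float)
    if np.isnan(Xq).any() or np.isnan(Xh).any():
        raise ValueError("cohorts must be imputed before coverage analysis")
    db = {**DEFAULT_DBSCAN, **(dbscan_params or {})}
    rng = np.random.default_rng(seed)
    covs = np.empty(n_boot)
    for r in range(n_boot):
        iq = (
            rng.integers(0, len(Xq), len(Xq))
            if resample == "both"
            else np.arange(len(Xq))
        )
        ih = (
            rng.integers(0, len(Xh), len(Xh))
            if resample in {"both", "hull"}
            else np.arange(len(Xh))
        )
        xh = Xh[ih]
        mu = xh.mean(axis=0)
        sd = xh.std(axis=0)
        if (sd == 0).any():
            const = fi if sd[0] == 0 else fj
            raise DegenerateHullError(
                f"feature {const!r} constant in hull sample of site "
                f"{hull.site_id!r} (replicate {r})"
            )
        zh = (xh - mu) / sd
        try:
            if denoise:
                zh = denoise_pair(
                    zh,
                    eps=db["eps"],
                    min_samples=db["min_samples"],
                    eps_quantile=db["eps_quantile"],
                )
            hull2d = build_hull(zh, feature_pair=(fi, fj))
        except (DegenerateHullError, ValueError) as exc:
            raise DegenerateHullError(
                f"pair ({fi!r}, {fj!r}), hull site {hull.site_id!r}, "
                f"replicate {r}: {exc}"
            ) from exc
        zq = (Xq[iq] - mu) / sd
        covs[r] = pair_coverage(zq, hull2d, tol=tol)
    return PairCoverage(
        query_site=query.site_id,
        hull_site=hull.site_id,
        feature_pair=(fi, fj),
        mean_coverage=float(covs.mean()),
        sd_coverage=float(covs.std(ddof=0)),
        n_boot=n_boot,
        seed=seed,
    )


def _pair_key(fi: str, fj: str) -> frozenset:
    return frozenset((fi, fj))


def feature_coverage(
    pair_coverages: Sequence[PairCoverage],
    features: Sequence[str],
    skipped: Sequence[tuple[str, str]] = (),
) -> FeatureCoverageDistribution:
    """Per-feature median coverages for one ordered site pair.

    Each feature's coverage is the median of the mean pair coverages over
    all feature pairs containing it; pairs listed in ``skipped``
    (degenerate hulls) are excluded from the requirement and from the
    medians. Every non-skipped pair must be present.
    """
    if not pair_coverages:
        raise ValueError("no pair coverages supplied")
    sites = {(pc.query_site, pc.hull_site) for pc in pair_coverages}
    if len(sites) != 1:
        raise ValueError(f"pair coverages mix site pairs: {sorted(sites)}")
    (query_site, hull_site) = next(iter(sites))
    by_pair = {_pair_key(*pc.feature_pair): pc.mean_coverage for pc in pair_coverages}
    skipped_keys = {_pair_key(*p) for p in skipped}
    for fi, fj in itertools.combinations(features, 2):
        key = _pair_key(fi, fj)
        if key not in by_pair and key not in skipped_keys:
            raise ValueError(f"missing pair coverage for features ({fi!r}, {fj!r})")
    per_feature = {}
    for f in features:
        vals = [
            v
            for key, v in by_pair.items()
            if f in key and key not in skipped_keys
        ]
        if vals:
            per_feature[f] = float(np.median(vals))
    if len(per_feature) >= 4:
        threshold, flagged = flag_low_coverage(per_feature)
    else:
        # quartiles are not meaningful below 4 features: no flagging
        threshold, flagged = None, frozenset()
    return FeatureCoverageDistribution(
        query_site=query_site,
        hull_site=hull_site,
        per_feature=per_feature,
        threshold=threshold,
        flagged=flagged,
        skipped_pairs=tuple(tuple(sorted(k)) for k in sorted(skipped_keys, key=sorted)),
    )


def _child_seed(seed: int, *key: str) -> int:
    """Deterministic per-cell stream keyed by site/feature identity, so
    permuting cohort input order permutes the matrix consistently."""
    import hashlib

    digest = hashlib.sha256("|".join(map(str, key)).encode()).digest()
    token = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(seed), token])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


class CoverageAnalysis:
    """Pairwise 2D convex-hull coverage over a set of prepared cohorts.

    Parameters
    ----------
    cohorts : sequence of CohortTable
        Feature-intersected, imputed cohorts (identical feature lists).
    n_boot : int
        Bootstrap replicates per feature pair (default 100).
    seed : int
        Master seed; every (site pair, feature pair) cell draws an
        independent child stream, so results are reproducible bit for bit.
    denoise : bool
        Apply DBSCAN to the hull-forming sample of every replicate.
    dbscan_params : mapping, optional
        Overrides for ``{"min_samples", "eps", "eps_quantile"}``.
    resample : str
        "both" (default), "hull" or "none"; see bootstrap_pair_coverage.
    """

    def __init__(
        self,
        cohorts: Sequence[CohortTable],
        n_boot: int = 100,
        seed: int = 0,
        denoise: bool = True,
        dbscan_params: Mapping | None = None,
        resample: str = "both",
    ) -> None:
        if len(cohorts) < 2:
            raise ValueError("need at least two cohorts")
        feats = cohorts[0].features
        for c in cohorts[1:]:
            if c.features != feats:
                raise ValueError(
                    "cohorts must share an identical, ordered feature list; "
                    "run intersect_features first"
                )
        for c in cohorts:
            if c.has_missing():
                raise ValueError(
                    f"site {c.site_id!r} has missing values; run impute_site_median first"
                )
        ids = [c.site_id for c in cohorts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site ids: {ids}")
        self.cohorts = list(cohorts)
        self.features = feats
        self.n_boot = int(n_boot)
        self.seed = int(seed)
        self.denoise = bool(denoise)
        self.dbscan_params = {**DEFAULT_DBSCAN, **(dbscan_params or {})}
        self.resample = resample

    def fit(self) -> "CoverageResults":
        sites = [c.site_id for c in self.cohorts]
        by_site = {c.site_id: c for c in self.cohorts}
        pair_coverages: dict[tuple[str, str], list[PairCoverage]] = {}
        distributions: dict[tuple[str, str], FeatureCoverageDistribution] = {}
        qc_log: list[dict] = []
        mat = pd.DataFrame(1.0, index=sites, columns=sites)
        mat.index.name = "query_site"
        mat.columns.name = "hull_site"
        for query in sites:
            for hull in sites:
                if query == hull:
                    continue
                pcs: list[PairCoverage] = []
                skipped: list[tuple[str, str]] = []
                for fi, fj in itertools.combinations(self.features, 2):
                    cell_seed = _child_seed(self.seed, query, hull, fi, fj)
                    try:
                        pcs.append(
                            bootstrap_pair_coverage(
                                by_site[query],
                                by_site[hull],
                                (fi, fj),
                                n_boot=self.n_boot,
                                seed=cell_seed,
                                denoise=self.denoise,
                                dbscan_params=self.dbscan_params,
                                resample=self.resample,
                            )
                        )
                    except DegenerateHullError as exc:
                        skipped.append((fi, fj))
                        qc_log.append(
                            {
                                "query_site": query,
                                "hull_site": hull,
                                "feature_i": fi,
                                "feature_j": fj,
                                "reason": str(exc),
                            }
                        )
                dist = feature_coverage(pcs, self.features, skipped=skipped)
                pair_coverages[(query, hull)] = pcs
                distributions[(query, hull)] = dist
                mat.loc[query, hull] = dist.mean_coverage
        matrix = SiteCoverageMatrix(sites=tuple(sites), values=mat)
        return CoverageResults(
            matrix=matrix,
            distributions=distributions,
            pair_coverages=pair_coverages,
            qc_log=qc_log,
            params=self.metadata(),
        )

    def metadata(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "denoise": self.denoise,
            "dbscan_params": dict(self.dbscan_params),
            "resample": self.resample,
            "quantile_method": QUANTILE_METHOD,
            "iqr_factor": IQR_FACTOR,
            "membership_tol": MEMBERSHIP_TOL,
        }


@dataclasses.dataclass
class CoverageResults:
    """Fitted coverage analysis: matrix, per-feature distributions, QC log."""

    matrix: SiteCoverageMatrix
    distributions: dict
    pair_coverages: dict
    qc_log: list
    params: dict

    def per_feature_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_site": q,
                "hull_site": h,
                "feature": f,
                "coverage": v,
                "threshold": d.threshold,
                "flagged": f in d.flagged,
            }
            for (q, h), d in sorted(self.distributions.items())
            for f, v in d.per_feature.items()
        ]
        return pd.DataFrame(rows)

    def flagged_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_site": q,
                "hull_site": h,
                "feature": f,
                "coverage": d.per_feature[f],
                "threshold": d.threshold,
            }
            for (q, h), d in sorted(self.distributions.items())
            for f in sorted(d.flagged)
        ]
        return pd.DataFrame(
            rows, columns=["query_site", "hull_site", "feature", "coverage", "threshold"]
        )

    def flagged_union(self, site_a: str, site_b: str) -> frozenset:
        """Union of flagged features over both directions of a site pair."""
        return frozenset(
            self.distributions[(site_a, site_b)].flagged
            | self.distributions[(site_b, site_a)].flagged
        )

    def pair_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_site": pc.query_site,
                "hull_site": pc.hull_site,
                "feature_i": pc.feature_pair[0],
                "feature_j": pc.feature_pair[1],
                "mean_coverage": pc.mean_coverage,
                "sd_coverage": pc.sd_coverage,
            }
            for pcs in self.pair_coverages.values()
            for pc in pcs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Convex-hull coverage (rows: query site, columns: hull site)", ""]
        lines.append(self.matrix.values.round(3).to_string())
        flagged = self.flagged_frame()
        lines.append("")
        if len(flagged):
            lines.append("Low-coverage features (below Q1 - 1.5*IQR):")
            lines.append(flagged.to_string(index=False))
        else:
            lines.append("Low-coverage features: none")
        if self.qc_log:
            lines.append(f"Skipped degenerate feature pairs: {len(self.qc_log)}")
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.values.to_csv(outdir / "coverage_matrix.csv")
        self.per_feature_frame().to_csv(outdir / "per_feature_coverage.csv", index=False)
        self.flagged_frame().to_csv(outdir / "flagged_features.csv", index=False)
        pd.DataFrame(
            self.qc_log,
            columns=["query_site", "hull_site", "feature_i", "feature_j", "reason"],
        ).to_csv(outdir / "qc_log.csv", index=False)

    def plot_heatmap(self, ax=None):
        """Heatmap of the site coverage matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        m = self.matrix.values
        im = ax.imshow(m.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(m.columns)), m.columns)
        ax.set_yticks(range(len(m.index)), m.index)
        ax.set_xlabel("hull site")
        ax.set_ylabel("query site")
        for i in range(len(m.index)):
            for j in range(len(m.columns)):
                ax.text(
                    j, i, f"{m.iat[i, j]:.2f}", ha="center", va="center", color="w"
                )
        ax.figure.colorbar(im, ax=ax, label="mean CH coverage")
        return ax


def coverage_matrix(
    cohorts: Sequence[CohortTable],
    n_boot: int = 100,
    seed: int = 0,
    denoise: bool = True,
    dbscan_params: Mapping | None = None,
    resample: str = "both",
) -> SiteCoverageMatrix:
    """Convenience wrapper: fitted SiteCoverageMatrix for a list of cohorts."""
    return (
        CoverageAnalysis(
            cohorts,
            n_boot=n_boot,
            seed=seed,
            denoise=denoise,
            dbscan_params=dbscan_params,
            resample=resample,
        )
        .fit()
        .matrix
    )
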