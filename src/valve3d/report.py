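"""Per-cusp reports, group comparisons and correlations.

Structural parameters are compared between diagnosis groups with
Mann-Whitney tests (exact for small samples, normal approximation with tie
correction otherwise) and related to each other with Pearson or Spearman
correlations. Group labels are opaque tags here: nothing in the package
depends on their clinical meaning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import __version__ as _pkg_version

__all__ = [
    "MannWhitneyResult",
    "mann_whitney",
    "correlate",
    "significance_stars",
    "CuspReport",
    "aggregate_valve",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float            # U statistic of the first group
    p: float            # two-sided
    method: str         # 'exact' or 'normal'

    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def _exact_mannwhitney_p(ranks2: np.ndarray, n_a: int, u_obs2: int) -> float:
    """Exact two-sided p over all group assignments, by dynamic programming.

    ``ranks2`` are pooled midranks times two (integers), so every achievable
    doubled rank sum is an integer and the tail comparison is exact. The DP
    table counts, for each subset size j and doubled rank sum s, the number
    of j-subsets of the pooled sample achieving s; the two-sided p is the
    probability mass at least as far from the null mean n_a*n_b/2 as the
    observed U (in doubled units).
    """
    total2 = int(ranks2.sum())
    n = len(ranks2)
    n_b = n - n_a
    # dp[j, s] = number of j-subsets with doubled rank sum s
    dp = np.zeros((n_a + 1, total2 + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total2 + 1 - r]
    counts = dp[n_a]
    sums2 = np.arange(total2 + 1)
    u2 = sums2 - n_a * (n_a + 1)          # doubled U for each doubled rank sum
    d_obs = abs(u_obs2 - n_a * n_b)       # doubled distance from the mean
    hits = counts[np.abs(u2 - n_a * n_b) >= d_obs].sum()
    return float(hits / counts.sum())


def mann_whitney(group_a, group_b, exact_max_n: int = 20) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test between two groups.

    For combined sample size up to ``exact_max_n`` the p-value is computed by
    exact enumeration of the permutation distribution (midranks handle ties);
    larger samples use the normal approximation with tie correction. The
    two-sided p is P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|), which for
    the untied exact case equals the familiar doubled one-sided tail.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(stats.rankdata(pooled) * 2).astype(np.int64)
    n_a = a.size
    u_obs2 = int(ranks2[:n_a].sum()) - n_a * (n_a + 1)
    u_obs = u_obs2 / 2.0
    if a.size + b.size <= exact_max_n:
        p = _exact_mannwhitney_p(ranks2, n_a, u_obs2)
        return MannWhitneyResult(u=u_obs, p=p, method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="normal")


def correlate(x_values, y_values, method: str = "pearson") -> tuple:
    """Pearson r or Spearman rho with the two-sided p; the method is explicit.

    Returns ``(coefficient, p, method)``. Raises on length mismatch, n < 3 or
    zero variance in either variable.
    """
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation coefficient undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), method


@dataclass
class CuspReport:
    """Every per-cusp quantity the pipeline computes, plus provenance."""

    sample_id: str
    valve_id: str
    group_tag: str
    cusp_volume_mm3: float
    calc_volume_mm3: float
    calc_volume_fraction: float
    density_volumes_mm3: dict          # hd/md/ld + direct
    volume_loss_fraction: float
    particle_summary: dict             # from ParticleTable.summary()
    thickness_summary: dict            # from thickness_summary()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-1e-9 <= self.calc_volume_fraction <= 1.0 + 1e-9):
            raise ValueError(
                f"calc_volume_fraction = {self.calc_volume_fraction} outside [0, 1]")
        # the correction can regain more volume than it removed (negative
        # loss) on isolated single-density particles; it only must be finite
        if not np.isfinite(self.volume_loss_fraction) or self.volume_loss_fraction > 1.0 + 1e-9:
            raise ValueError(
                f"volume_loss_fraction = {self.volume_loss_fraction} invalid")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def make_provenance(config, volume_data: np.ndarray | None = None) -> dict:
    prov = {"software_version": _pkg_version, "config": config.to_dict()}
    if volume_data is not None:
        prov["input_sha256"] = hashlib.sha256(
            np.ascontiguousarray(volume_data).tobytes()).hexdigest()
    return prov


def aggregate_valve(cusp_reports) -> dict:
    """Valve-level record pooled over its cusps.

    The valve calcification fraction is the pooled ratio (sum of
    calcification volumes over sum of cusp volumes), so it always lies
    between the smallest and largest per-cusp fraction.
    """
    reports = list(cusp_reports)
    if not reports:
        raise ValueError("no cusp reports supplied")
    valve_ids = {r.valve_id for r in reports}
    if len(valve_ids) != 1:
        raise ValueError(f"mixed valve ids: {sorted(valve_ids)}")
    if not (1 <= len(reports) <= 3):
        raise ValueError("a valve has 1-3 cusps")
    calc = sum(r.calc_volume_mm3 for r in reports)
    cusp = sum(r.cusp_volume_mm3 for r in reports)
    return {
        "valve_id": reports[0].valve_id,
        "group_tag": reports[0].group_tag,
        "n_cusps": len(reports),
        "cusp_volume_mm3": cusp,
        "calc_volume_mm3": calc,
        "calc_volume_fraction": calc / cusp,
    }
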