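"""Direct vs confounded associations between gene features and expression.

The central tool is the Spearman partial correlation: the correlation
between two variables after removing, by linear regression on ranks, the
contribution of a control set. Three interchangeable routes are provided —

``residual``
    rank-transform all columns, regress x and y on the controls (with
    intercept), then apply the product-moment estimator to the residuals;
``recursive``
    reduce the order-n partial correlation to three order-(n-1) ones via
    rho_xy.Z = (rho_xy.Z' - rho_xz0.Z' rho_z0y.Z')
              / sqrt((1 - rho_xz0.Z'^2)(1 - rho_z0y.Z'^2)),  Z' = Z \\ {z0};
``matrix``
    invert the Spearman correlation matrix of {x, y} + controls and read
    the partial correlation off the precision matrix (the oracle route).

All three agree to numerical precision on nondegenerate data, which the
test suite asserts. Also here: correlation/partial-correlation networks,
2x2 contingency enrichment, two-sample Hotelling T^2, stratified empirical
CDFs with KS statistics, and a simple per-gene Welch-t differential test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CollinearityError(ValueError):
    pass


class DegenerateControlError(ValueError):
    pass


def prepare_features(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Listwise-drop rows with missing values in the named columns.

    Returns the cleaned frame; the number of dropped rows is recorded in
    ``.attrs['n_dropped']``.
    """
    sub = df[list(variables)].apply(pd.to_numeric)
    clean = sub.dropna()
    clean.attrs["n_dropped"] = len(sub) - len(clean)
    if len(clean) < 3:
        raise ValueError("fewer than 3 complete rows; cannot correlate")
    return clean


def _rank(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (midranks for ties)."""
    return np.apply_along_axis(stats.rankdata, 0, np.asarray(a, float))


def spearman_matrix(fm: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix: average ranks, then Pearson on ranks.

    Constant columns get NaN correlations (flagged, not an error)."""
    if len(fm) < 3:
        raise ValueError("need at least 3 rows")
    ranks = _rank(fm.to_numpy())
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    const = sd == 0
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, np.where(const, np.nan, 1.0))
    return pd.DataFrame(corr, index=fm.columns, columns=fm.columns)


@dataclass
class PartialCorrResult:
    x: str
    y: str
    controls: tuple
    rho_xy: float
    rho_xy_given_z: float
    method: str
    n: int
    intermediates: dict = field(default_factory=dict)


def _product_moment(rx: np.ndarray, ry: np.ndarray) -> float:
    """The product-moment estimator in its summation form,
    (N*Sxy - Sx*Sy) / sqrt((N*Sxx - Sx^2)(N*Syy - Sy^2))."""
    n = len(rx)
    sx, sy = rx.sum(), ry.sum()
    sxx, syy, sxy = (rx * rx).sum(), (ry * ry).sum(), (rx * ry).sum()
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    if den == 0:
        raise DegenerateControlError(
            "zero residual variance: a variable is fully explained by the "
            "controls")
    return float((n * sxy - sx * sy) / den)


def _residual_route(ranks: np.ndarray, ix: int, iy: int,
                    ic: list[int]) -> tuple[float, dict]:
    n = ranks.shape[0]
    Z = np.column_stack([np.ones(n)] + [ranks[:, k] for k in ic])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError("control columns are collinear")
    wx, *_ = np.linalg.lstsq(Z, ranks[:, ix], rcond=None)
    wy, *_ = np.linalg.lstsq(Z, ranks[:, iy], rcond=None)
    rx = ranks[:, ix] - Z @ wx
    ry = ranks[:, iy] - Z @ wy
    for r, k in ((rx, ix), (ry, iy)):
        if np.var(r) <= 1e-16 * np.var(ranks[:, k]):
            raise DegenerateControlError(
                "zero residual variance: a variable is fully explained by "
                "the controls")
    rho = _product_moment(rx, ry)
    return rho, {"weights_x": wx, "weights_y": wy,
                 "resid_x": rx, "resid_y": ry, "design": Z}


def _recursive_route(corr: np.ndarray, ix: int, iy: int,
                     ic: tuple[int, ...], _memo=None) -> float:
    if _memo is None:
        _memo = {}
    key = (min(ix, iy), max(ix, iy), ic)
    if key in _memo:
        return _memo[key]
    if not ic:
        val = corr[ix, iy]
    else:
        z0, rest = ic[0], ic[1:]
        r_xy = _recursive_route(corr, ix, iy, rest, _memo)
        r_xz = _recursive_route(corr, ix, z0, rest, _memo)
        r_zy = _recursive_route(corr, z0, iy, rest, _memo)
        den = np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_zy ** 2))
        if den == 0 or not np.isfinite(den):
            raise DegenerateControlError(
                "recursive reduction hit |rho| = 1 with a control")
        val = (r_xy - r_xz * r_zy) / den
    _memo[key] = val
    return val


def _matrix_route(corr: np.ndarray, ix: int, iy: int,
                  ic: list[int]) -> float:
    idx = [ix, iy] + list(ic)
    sub = corr[np.ix_(idx, idx)]
    if np.linalg.cond(sub) > 1e12:
        raise CollinearityError(
            "correlation submatrix is (numerically) singular — collinear "
            "variables")
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as e:
        raise CollinearityError(f"singular correlation submatrix: {e}") from e
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def partial_correlation(fm: pd.DataFrame, x: str, y: str,
                        controls: Sequence[str] = (),
                        method: str = "residual") -> PartialCorrResult:
    """Spearman partial correlation of ``x`` and ``y`` given ``controls``.

    With an empty control set all methods reduce to the plain Spearman
    correlation. Controls are eliminated in the given order by the
    recursive route (the result is order-invariant).
    """
    controls = tuple(controls)
    if x in controls or y in controls:
        raise ValueError("x and y must not appear among the controls")
    if x == y:
        raise ValueError("x and y must differ")
    if method not in ("residual", "recursive", "matrix"):
        raise ValueError(f"unknown method {method!r}")
    cols = [x, y] + list(controls)
    fm = prepare_features(fm, cols)
    n = len(fm)
    if n <= len(controls) + 2:
        raise ValueError(
            f"need n > |controls| + 2 rows; got n={n}, "
            f"|controls|={len(controls)}")
    ranks = _rank(fm.to_numpy())
    if np.any(ranks.std(axis=0) == 0):
        bad = [cols[k] for k in np.flatnonzero(ranks.std(axis=0) == 0)]
        raise DegenerateControlError(f"constant columns: {bad}")
    corr = np.corrcoef(ranks, rowvar=False)
    ix, iy, ic = 0, 1, list(range(2, 2 + len(controls)))
    rho_xy = float(corr[ix, iy])

    intermediates: dict = {}
    if method == "residual":
        rho, intermediates = _residual_route(ranks, ix, iy, ic)
    elif method == "recursive":
        rho = float(_recursive_route(corr, ix, iy, tuple(ic)))
    else:
        rho = _matrix_route(corr, ix, iy, ic)
    rho = float(np.clip(rho, -1.0, 1.0))
    return PartialCorrResult(x=x, y=y, controls=controls, rho_xy=rho_xy,
                             rho_xy_given_z=rho, method=method, n=n,
                             intermediates=intermediates)


def correlation_null_band(n: int, n_controls: int = 0,
                          alpha: float = 0.01) -> float:
    """Half-width of the null (1-alpha) band for a (partial) correlation at
    sample size n, from the Fisher z approximation."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(np.tanh(z / np.sqrt(n - n_controls - 3)))


# ---------------------------------------------------------------------------
# networks

@dataclass(frozen=True)
class NetworkEdge:
    u: str
    v: str
    correlation: float
    partial_correlation: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.partial_correlation))


@dataclass
class CorrelationNetwork:
    nodes: list            # (variable name, class tag)
    edges: list            # NetworkEdge, u < v

    def edge(self, u: str, v: str) -> NetworkEdge:
        u, v = sorted((u, v))
        for e in self.edges:
            if (e.u, e.v) == (u, v):
                return e
        raise KeyError((u, v))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "u": e.u, "v": e.v, "correlation": e.correlation,
            "partial_correlation": e.partial_correlation, "sign": e.sign,
        } for e in self.edges])


def pcor_network(fm: pd.DataFrame, variables: Sequence[str],
                 classes: Optional[Mapping[str, str]] = None,
                 method: str = "residual") -> CorrelationNetwork:
    """Each pair of variables gets its pairwise Spearman correlation and
    the partial correlation controlling all remaining listed variables."""
    variables = list(variables)
    if len(variables) < 3:
        raise ValueError("need at least 3 variables for a network")
    fm = prepare_features(fm, variables)
    edges = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            x, y = variables[i], variables[j]
            controls = [v for v in variables if v not in (x, y)]
            res = partial_correlation(fm, x, y, controls, method=method)
            u, v = sorted((x, y))
            edges.append(NetworkEdge(u, v, res.rho_xy, res.rho_xy_given_z))
    nodes = [(v, (classes or {}).get(v, "feature")) for v in variables]
    return CorrelationNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# contingency enrichment

@dataclass(frozen=True)
class ContingencyResult:
    table: tuple           # ((sites&down, sites&up), (nosites&down, nosites&up))
    odds_ratio: float
    p_value: float
    prop_down_with_sites: float
    prop_down_without_sites: float

    @property
    def ratio_down(self) -> float:
        """How much more often genes with sites are downregulated."""
        if self.prop_down_without_sites == 0:
            return float("inf")
        return self.prop_down_with_sites / self.prop_down_without_sites


def contingency_enrichment(has_sites, direction) -> ContingencyResult:
    """2x2 enrichment of regulation direction by site presence.

    ``has_sites`` is boolean per gene; ``direction`` is 'down'/'up' (or a
    boolean is-down flag). Odds ratio uses a Haldane 0.5 correction when a
    cell is zero; the p value is a two-sided Fisher exact test.
    """
    has_sites = np.asarray(has_sites, dtype=bool)
    direction = np.asarray(direction)
    if direction.dtype.kind in "US":
        is_down = direction == "down"
        if not np.all(np.isin(direction, ["down", "up"])):
            raise ValueError("direction entries must be 'down' or 'up'")
    else:
        is_down = direction.astype(bool)
    if has_sites.shape != is_down.shape:
        raise ValueError("has_sites and direction must align")

    a = int(np.sum(has_sites & is_down))
    b = int(np.sum(has_sites & ~is_down))
    c = int(np.sum(~has_sites & is_down))
    d = int(np.sum(~has_sites & ~is_down))
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("contingency table has an empty margin")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(
        table=((a, b), (c, d)), odds_ratio=float(orr), p_value=float(p),
        prop_down_with_sites=a / (a + b),
        prop_down_without_sites=c / (c + d))


# ---------------------------------------------------------------------------
# Hotelling T^2

@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    p_value: float
    df1: int
    df2: int


def hotelling_t2(group_a, group_b) -> HotellingResult:
    """Two-sample Hotelling T^2 with pooled covariance (2D points).

    The p value comes from the exact transform
    F = (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) * T^2 ~ F(p, n1 + n2 - p - 1).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("groups must be (n, 2) arrays of paired values")
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs at least 3 points")
    p = 2
    d = a.mean(axis=0) - b.mean(axis=0)
    S = ((n1 - 1) * np.cov(a, rowvar=False)
         + (n2 - 1) * np.cov(b, rowvar=False)) / (n1 + n2 - 2)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular pooled covariance: {e}") from e
    t2 = float((n1 * n2) / (n1 + n2) * d @ Sinv @ d)
    df2 = n1 + n2 - p - 1
    f = t2 * df2 / (p * (n1 + n2 - 2))
    pval = float(stats.f.sf(f, p, df2))
    return HotellingResult(t2=t2, f_stat=float(f), p_value=pval,
                           df1=p, df2=df2)


def bonferroni(p_values, m: Optional[int] = None) -> np.ndarray:
    p = np.asarray(p_values, float)
    m = m if m is not None else p.size
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# stratified CDFs

@dataclass
class StratifiedCdf:
    cdfs: dict             # group -> DataFrame(value, cdf)
    ks: dict               # group -> (statistic, p) vs reference
    reference: str
    dropped: list


def stratified_cdf(values, groups, reference: Optional[str] = None) -> StratifiedCdf:
    """Per-group empirical CDFs and two-sample KS statistics vs a reference
    group (default: first group in order of appearance). Empty groups are
    dropped with a warning."""
    import warnings

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    finite = np.isfinite(values)
    order = list(pd.unique(groups))
    by_group = {g: values[(groups == g) & finite] for g in order}
    dropped = [g for g, v in by_group.items() if len(v) == 0]
    if dropped:
        warnings.warn(f"dropped empty groups: {dropped}", stacklevel=2)
        for g in dropped:
            by_group.pop(g)
    if len(by_group) < 2:
        raise ValueError("need at least 2 nonempty groups")
    ref = reference if reference is not None else next(iter(by_group))
    if ref not in by_group:
        raise ValueError(f"reference group {ref!r} not present")

    cdfs, ks = {}, {}
    for g, v in by_group.items():
        v = np.sort(v)
        cdfs[g] = pd.DataFrame({
            "value": v, "cdf": np.arange(1, len(v) + 1) / len(v)})
        if g == ref:
            ks[g] = (0.0, 1.0)
        else:
            stat, pval = stats.ks_2samp(v, by_group[ref])
            ks[g] = (float(stat), float(pval))
    return StratifiedCdf(cdfs=cdfs, ks=ks, reference=ref, dropped=dropped)


# ---------------------------------------------------------------------------
# simple differential expression stand-in

def simple_de(replicate_matrix, group_labels,
              gene_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-gene Welch t-test between two replicate groups with Bonferroni
    correction — a simple stand-in for a full microarray pipeline.

    ``replicate_matrix`` is (genes x replicates) of log2 intensities;
    ``group_labels`` names each column; log2FC is the second group's mean
    minus the first's (first label in order of appearance = baseline).
    Genes with zero variance in both groups get NaN p values (flagged).
    """
    X = np.asarray(replicate_matrix, float)
    labels = np.asarray(group_labels)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    ga, gb = X[:, labels == uniq[0]], X[:, labels == uniq[1]]
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    log2fc = gb.mean(axis=1) - ga.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(gb, ga, axis=1, equal_var=False)
    scale = np.maximum(np.abs(X).max(axis=1), 1.0)
    degenerate = (ga.std(axis=1) <= 1e-12 * scale) \
        & (gb.std(axis=1) <= 1e-12 * scale)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    out = pd.DataFrame({
        "log2fc": log2fc, "t_stat": t, "p_value": p,
        "p_bonferroni": bonferroni(p, X.shape[0])})
    if gene_ids is not None:
        out.insert(0, "gene_id", list(gene_ids))
    return out
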