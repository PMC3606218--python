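"""Covaried group statistics on lobar and regional fiber counts.

The analysis ladder mirrors a two-step whole-brain connectome
comparison at desk scale:

1. **Global** — ANCOVA of the total fiber count on group, covaried for
   age and sex; the adjusted patient/control ratio (in percent) is the
   *global* difference every other percentage is referenced to.
2. **Lobar** — the 70-node matrix is aggregated into 10 lobe-hemisphere
   units (5 lobes x 2 hemispheres); three connection families — 15
   right-hemisphere pairs, 15 left-hemisphere pairs, 25 inter-
   hemispheric L-lobe x R-lobe pairs — are each tested with a MANCOVA
   (Wilks' lambda, Rao's F approximation) covaried for age, sex and the
   total fiber count, followed by per-connection univariate ANCOVAs.
3. **Regional post-hoc** — inside each significant lobe pair, the
   per-parcel fiber totals restricted to that pair's span are tested
   with the same covaried ANCOVA; unreliable parcels (frontal/temporal
   poles, banks of the superior temporal sulcus) are excluded.

Per-connection differences are reported as *absolute* percentages
(adjusted patient mean / adjusted control mean x 100) and *relative*
percentages (absolute minus the global percentage), so a connection
moving with the global reduction scores a relative difference of zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import LOBES, Parcellation
from .connectome import ConnectionMatrix
from .edge_filter import EdgeMask, apply_mask

__all__ = [
    "LobarMatrix",
    "StatTestResult",
    "DifferenceReport",
    "RegressionResult",
    "aggregate_to_lobes",
    "ancova_group_difference",
    "mancova_wilks",
    "lobar_analysis",
    "regional_posthoc",
    "difference_percentages",
    "correct_multiple",
    "age_regressions",
    "adjusted_group_means",
    "lobar_connection_families",
]


@dataclass
class LobarMatrix:
    """Symmetric 10x10 fiber-count matrix over lobe-hemisphere units."""

    units: list[tuple[str, str]]
    count: np.ndarray
    subject_id: str = "subject"

    def total(self) -> float:
        return float(np.triu(self.count).sum())


@dataclass
class StatTestResult:
    connection: str
    F: float
    p: float
    df: tuple[float, float]
    significant_fdr: bool = False
    significant_bonferroni: bool = False
    family: str = ""


@dataclass
class DifferenceReport:
    connection: str
    absolute_pct: float
    relative_pct: float
    global_pct: float
    family: str = ""


@dataclass
class RegressionResult:
    measure: str
    group: str
    R: float
    p: float


@dataclass
class MancovaResult:
    family: str
    wilks_lambda: float
    F: float
    p: float
    df: tuple[float, float]


# ----------------------------------------------------------------------
# aggregation


def aggregate_to_lobes(
    matrix: ConnectionMatrix,
    parcellation: Parcellation,
    mask: Optional[EdgeMask] = None,
) -> LobarMatrix:
    """Sum masked node-pair counts into the 10-unit lobar matrix.

    Each node pair contributes to exactly one lobar cell; intra-ROI
    diagonal cells contribute to their lobe's intra-lobe cell, so the
    aggregation conserves subject totals under an all-keep mask.
    Masked (excluded) cells contribute nothing.
    """
    units = parcellation.lobar_units()
    unit_of = parcellation.node_unit_indices()
    counts = matrix.count.astype(float)
    if mask is not None:
        counts = apply_mask(counts, mask)
    n_units = len(units)
    out = np.zeros((n_units, n_units))
    n = matrix.n_nodes
    iu, ju = np.triu_indices(n)
    vals = counts[iu, ju]
    ok = ~np.isnan(vals)
    for i, j, v in zip(unit_of[iu[ok]], unit_of[ju[ok]], vals[ok]):
        a, b = min(i, j), max(i, j)
        out[a, b] += v
    out = out + np.triu(out, 1).T
    return LobarMatrix(units=units, count=out, subject_id=matrix.subject_id)


def lobar_connection_families(units: Sequence[tuple[str, str]]) -> dict[str, list[tuple[int, int]]]:
    """The three tested families as unit-index pairs.

    Within each hemisphere all C(5,2)+5 = 15 unordered lobe pairs
    (including intra-lobe cells); across hemispheres all 5x5 = 25
    L-lobe x R-lobe combinations.
    """
    by_hemi = {h: [k for k, (_, hh) in enumerate(units) if hh == h] for h in ("L", "R")}
    fams: dict[str, list[tuple[int, int]]] = {}
    for h, name in (("R", "right_hemisphere"), ("L", "left_hemisphere")):
        idx = by_hemi[h]
        fams[name] = list(itertools.combinations_with_replacement(idx, 2))
    fams["inter_hemisphere"] = [(i, j) for i in by_hemi["L"] for j in by_hemi["R"]]
    return fams


def connection_label(units: Sequence[tuple[str, str]], pair: tuple[int, int]) -> str:
    (la, ha), (lb, hb) = units[pair[0]], units[pair[1]]
    return f"{la}-{ha}:{lb}-{hb}"


# ----------------------------------------------------------------------
# models


def _design(subjects: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    group = (subjects["group"].to_numpy() == "patient").astype(float)
    cols = [np.ones(len(subjects)), group]
    cols += [subjects[c].to_numpy(dtype=float) for c in covariates]
    return np.column_stack(cols)


def ancova_group_difference(
    response: np.ndarray,
    subjects: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    connection: str = "response",
) -> StatTestResult:
    """ANCOVA: response ~ group + covariates; partial (type-III) F for group.

    Group is coded 0 (control) / 1 (patient); with a single 0/1 term
    the type-III F equals the squared t of its coefficient.
    """
    y = np.asarray(response, dtype=float)
    counts = subjects["group"].value_counts()
    if counts.get("patient", 0) < 2 or counts.get("control", 0) < 2:
        raise ValueError("need >= 2 subjects per group")
    X = _design(subjects, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: check for constant covariates or a "
            "single-sex group"
        )
    fit = sm.OLS(y, X).fit()
    df_denom = float(len(y) - X.shape[1])
    # degenerate zero-noise responses make the F ratio 0/0; when the group
    # term's extra sum of squares is negligible against the null model the
    # statistic is zero by definition
    fit0 = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    ess = fit0.ssr - fit.ssr
    if ess <= 1e-12 * max(fit0.ssr, np.finfo(float).tiny):
        return StatTestResult(connection, 0.0, 1.0, (1.0, df_denom))
    ft = fit.f_test(np.eye(X.shape[1])[1])  # the group column
    return StatTestResult(
        connection=connection,
        F=float(ft.fvalue),
        p=float(ft.pvalue),
        df=(float(ft.df_num), float(ft.df_denom)),
    )


def mancova_wilks(
    responses: np.ndarray,
    subjects: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "total_fibers"),
    family: str = "family",
) -> MancovaResult:
    """Multivariate ANCOVA for the group term via Wilks' lambda.

    Fits Y = XB + E with X = [1, group, covariates]; the hypothesis
    SSCP H is the reduction in the error SSCP E when the group column
    enters.  Λ = det(E)/det(H+E); the p-value uses Rao's F
    approximation, exact here because the hypothesis has one degree of
    freedom.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    X = _design(subjects, covariates)
    k = X.shape[1]
    if n <= p + k:
        raise ValueError(
            f"too few subjects ({n}) for {p} responses and {k - 2} covariates; "
            "reduce the response set"
        )
    X0 = np.delete(X, 1, axis=1)  # null model without group

    def sscp(Xd: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        resid = Y - Xd @ beta
        return resid.T @ resid

    E = sscp(X)
    E0 = sscp(X0)
    H = E0 - E
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError("singular error matrix: reduce the number of responses")
    _, logdet_HE = np.linalg.slogdet(H + E)
    lam = float(np.exp(logdet_E - logdet_HE))
    lam = min(max(lam, 0.0), 1.0)

    q = 1.0  # hypothesis df (one group contrast)
    v = float(n - k)  # error df
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    w = v + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q) / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    pval = float(scipy.stats.f.sf(F, df1, df2))
    return MancovaResult(
        family=family, wilks_lambda=lam, F=float(F), p=pval, df=(df1, df2)
    )


def adjusted_group_means(
    response: np.ndarray,
    subjects: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
) -> tuple[float, float]:
    """Least-squares means at the covariate grand means: (patient, control)."""
    y = np.asarray(response, dtype=float)
    X = _design(subjects, covariates)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    grand = X.mean(axis=0)
    base = float(beta[0] + grand[2:] @ beta[2:]) if len(beta) > 2 else float(beta[0])
    control = base
    patient = base + float(beta[1])
    return patient, control


def raw_group_means(response: np.ndarray, subjects: pd.DataFrame) -> tuple[float, float]:
    y = np.asarray(response, dtype=float)
    g = subjects["group"].to_numpy()
    return float(y[g == "patient"].mean()), float(y[g == "control"].mean())


def difference_percentages(
    patient_mean: float, control_mean: float, global_pct: float, connection: str = ""
) -> Optional[DifferenceReport]:
    """Absolute (patient/control x 100) and relative (absolute - global) %.

    Returns ``None`` when the control mean is not positive (the ratio
    is undefined and the connection is reported as missing).
    """
    if control_mean <= 0:
        return None
    absolute = 100.0 * patient_mean / control_mean
    return DifferenceReport(
        connection=connection,
        absolute_pct=absolute,
        relative_pct=absolute - global_pct,
        global_pct=global_pct,
    )


def correct_multiple(
    p_values: Sequence[float], method: str = "fdr_bh", alpha: float = 0.05
) -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni rejection flags at level alpha."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")
    reject, *_ = multipletests(p, alpha=alpha, method=method)
    return reject


# ----------------------------------------------------------------------
# pipeline-level analyses


def _subject_frame(
    subjects: pd.DataFrame, matrices: dict[str, ConnectionMatrix]
) -> pd.DataFrame:
    """Subject table ordered to match extraction, with unmasked totals."""
    df = subjects.copy().reset_index(drop=True)
    totals = np.array([matrices[sid].total_fibers() for sid in df["id"]], dtype=float)
    df["total_fibers"] = totals
    return df


def global_ancova(
    subjects: pd.DataFrame,
    matrices: dict[str, ConnectionMatrix],
    use_adjusted_means: bool = True,
) -> tuple[StatTestResult, float]:
    """Global ANCOVA on total fibers; returns (test, global percentage)."""
    df = _subject_frame(subjects, matrices)
    totals = df["total_fibers"].to_numpy()
    res = ancova_group_difference(totals, df, ("age", "sex"), "total_fibers")
    res.family = "global"
    if use_adjusted_means:
        pt, ct = adjusted_group_means(totals, df, ("age", "sex"))
    else:
        pt, ct = raw_group_means(totals, df)
    return res, 100.0 * pt / ct


def lobar_analysis(
    subjects: pd.DataFrame,
    matrices: dict[str, ConnectionMatrix],
    parcellation: Parcellation,
    mask: Optional[EdgeMask] = None,
    alpha: float = 0.05,
    use_adjusted_means: bool = True,
) -> dict:
    """Global + lobar analysis ladder.

    Returns a dict with the global test and percentage, the three
    family MANCOVAs, per-connection univariate results with FDR and
    Bonferroni flags (within family), and difference reports.
    """
    df = _subject_frame(subjects, matrices)
    glob, global_pct = global_ancova(subjects, matrices, use_adjusted_means)

    lobar = {sid: aggregate_to_lobes(matrices[sid], parcellation, mask) for sid in df["id"]}
    units = next(iter(lobar.values())).units
    stack = np.stack([lobar[sid].count for sid in df["id"]])  # (n_sub, 10, 10)
    families = lobar_connection_families(units)

    mancovas: list[MancovaResult] = []
    tests: list[StatTestResult] = []
    reports: list[DifferenceReport] = []
    for fam_name, pairs in families.items():
        Y = np.stack([stack[:, i, j] for i, j in pairs], axis=1)
        mancovas.append(mancova_wilks(Y, df, ("age", "sex", "total_fibers"), fam_name))
        fam_tests = []
        for col, pair in enumerate(pairs):
            label = connection_label(units, pair)
            t = ancova_group_difference(
                Y[:, col], df, ("age", "sex", "total_fibers"), label
            )
            t.family = fam_name
            fam_tests.append(t)
            # percentages are age/sex-adjusted only: conditioning on total
            # fibers would re-centre every ratio at ~100% and hide the
            # global reduction the relative percentage is defined against
            if use_adjusted_means:
                pt, ct = adjusted_group_means(Y[:, col], df, ("age", "sex"))
            else:
                pt, ct = raw_group_means(Y[:, col], df)
            rep = difference_percentages(pt, ct, global_pct, label)
            if rep is not None:
                rep.family = fam_name
                reports.append(rep)
        pvals = [t.p for t in fam_tests]
        for t, fdr, bonf in zip(
            fam_tests,
            correct_multiple(pvals, "fdr_bh", alpha),
            correct_multiple(pvals, "bonferroni", alpha),
        ):
            t.significant_fdr = bool(fdr)
            t.significant_bonferroni = bool(bonf)
        tests.extend(fam_tests)

    return dict(
        global_test=glob,
        global_pct=global_pct,
        mancovas=mancovas,
        connection_tests=tests,
        difference_reports=reports,
        units=units,
        families=families,
    )


def regional_posthoc(
    subjects: pd.DataFrame,
    matrices: dict[str, ConnectionMatrix],
    parcellation: Parcellation,
    significant_pairs: Sequence[tuple[int, int]],
    mask: Optional[EdgeMask] = None,
    alpha: float = 0.05,
    use_adjusted_means: bool = True,
) -> tuple[list[StatTestResult], list[DifferenceReport]]:
    """Per-parcel follow-up inside significant lobe pairs.

    For a significant pair (a, b), every non-excluded parcel in unit a
    (and in unit b) is tested on its fiber total restricted to the
    pair's span: the sum of masked cells between the parcel and all
    nodes of the opposite unit (for a == b, within the unit).  Models
    are ANCOVAs covaried for age, sex and total fibers; corrections are
    applied across all tested parcels.
    """
    if len(significant_pairs) == 0:
        return [], []
    df = _subject_frame(subjects, matrices)
    _, global_pct = global_ancova(subjects, matrices, use_adjusted_means)
    units = parcellation.lobar_units()
    unit_of = parcellation.node_unit_indices()
    excluded = parcellation.roi_table["excluded"].to_numpy()
    names = parcellation.roi_table["name"].to_list()

    masked = {}
    for sid in df["id"]:
        counts = matrices[sid].count.astype(float)
        masked[sid] = apply_mask(counts, mask) if mask is not None else counts

    tests: list[StatTestResult] = []
    reports: list[DifferenceReport] = []
    seen: set[tuple[int, int]] = set()
    for a, b in significant_pairs:
        for parcel_unit, span_unit in dict.fromkeys([(a, b), (b, a)]):
            parcels = np.where((unit_of == parcel_unit) & ~excluded)[0]
            span = np.where(unit_of == span_unit)[0]
            for pi in parcels:
                key = (pi, span_unit)
                if key in seen:
                    continue
                seen.add(key)
                y = np.array(
                    [np.nansum(masked[sid][pi, span]) for sid in df["id"]]
                )
                label = f"{names[pi]}|span={units[span_unit][0]}-{units[span_unit][1]}"
                t = ancova_group_difference(y, df, ("age", "sex", "total_fibers"), label)
                t.family = "regional"
                tests.append(t)
                if use_adjusted_means:
                    pt, ct = adjusted_group_means(y, df, ("age", "sex"))
                else:
                    pt, ct = raw_group_means(y, df)
                rep = difference_percentages(pt, ct, global_pct, label)
                if rep is not None:
                    rep.family = "regional"
                    reports.append(rep)
    pvals = [t.p for t in tests]
    for t, fdr, bonf in zip(
        tests,
        correct_multiple(pvals, "fdr_bh", alpha),
        correct_multiple(pvals, "bonferroni", alpha),
    ):
        t.significant_fdr = bool(fdr)
        t.significant_bonferroni = bool(bonf)
    return tests, reports


def age_regressions(
    subjects: pd.DataFrame,
    measures: Sequence[str] = ("mean_fa", "white_matter_volume", "total_fibers"),
    one_sided: bool = False,
) -> list[RegressionResult]:
    """Per-group OLS of each white-matter measure on age.

    Reports the Pearson correlation R and its p-value (two-sided by
    default; ``one_sided=True`` halves it in the direction of the
    observed slope).
    """
    out = []
    for gname, sub in subjects.groupby("group", sort=True):
        if len(sub) < 3:
            raise ValueError("need >= 3 subjects per group")
        age = sub["age"].to_numpy(dtype=float)
        if np.ptp(age) == 0:
            raise ValueError("constant age: regression undefined")
        for m in measures:
            y = sub[m].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = scipy.stats.pearsonr(age, y)
            if one_sided:
                p = p / 2.0
            out.append(RegressionResult(measure=m, group=str(gname), R=float(r), p=float(p)))
    return out
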