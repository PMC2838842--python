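"""Genewise ANOVA models for dual-color expression data.

For every probe, the log2 channel intensities y are modeled as

    y = mu + tau_i + eta_j + alpha_k + eps,        (ratio-based model)
    y = mu + tau_i + eta_j + eps,                  (intensity-based model)

where ``tau_i`` is the treatment (group) effect of interest, ``eta_j`` an
optional experimental-unit (cell line) effect, ``alpha_k`` a per-gene array
effect, and ``eps`` Gaussian noise.  Including the array effect makes the
analysis equivalent to working on within-array log-ratios; omitting it
treats the single channels as exchangeable observations.  Dye terms are not
modeled: designs are expected to be dye-balanced and normalization removes
dye-specific bias.

Treatment significance comes from the extra-sum-of-squares F-test against
the same model with the treatment factor removed.  Per-probe BIC values of
the two models (Gaussian maximum-likelihood, parameter count = retained
mean parameters + 1 for the residual variance) drive model selection: the
lower BIC wins, ties go to the more parsimonious intensity model.

Rank deficiency — e.g. treatment partially confounded with arrays — is
handled by fitting with the Moore-Penrose pseudo-inverse (minimum-norm
coefficients; estimable contrasts are unique) and reporting aliased columns
detected by pivoted QR, never silently.  No multiple-testing correction is
applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .design import ChannelKey, HybridizationDesign
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

MODEL_RATIO = "ratio"
MODEL_INTENSITY = "intensity"

_RSS_ATOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Which effects enter the genewise linear model.

    The ratio spec differs from the intensity spec only by ``include_array``.
    """

    include_array: bool
    include_unit: bool = False

    @property
    def name(self) -> str:
        return MODEL_RATIO if self.include_array else MODEL_INTENSITY


def ratio_spec(include_unit: bool = False) -> ModelSpec:
    """Model with the per-gene array effect (ratio-based analysis)."""
    return ModelSpec(include_array=True, include_unit=include_unit)


def intensity_spec(include_unit: bool = False) -> ModelSpec:
    """Model without the array effect (intensity-based analysis)."""
    return ModelSpec(include_array=False, include_unit=include_unit)


class DesignMatrixBundle:
    """Model matrix for one design/spec pair, shared by every probe.

    Treatment and unit factors use reference-level (treatment-contrast)
    coding; the array factor uses full indicator coding, whose redundancy
    with the intercept is resolved by the pseudo-inverse and surfaced in the
    aliasing report.  ``rank`` is the dimension of the column space after
    aliasing; ``aliased`` lists the labels pivoted QR identified as linearly
    dependent on earlier columns.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        labels: list[str],
        channels: list[ChannelKey],
        treatment_levels: list[str],
        treatment_cols: dict[str, int],
        array_cols: dict[str, int],
        spec: ModelSpec,
    ):
        self.matrix = np.asarray(matrix, dtype=float)
        self.labels = labels
        self.channels = channels
        self.treatment_levels = treatment_levels
        self._treatment_cols = treatment_cols  # level -> column (ref level absent)
        self.array_cols = array_cols
        self.spec = spec
        self.rank = int(np.linalg.matrix_rank(self.matrix))
        self.aliased = self._aliasing_report()

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @cached_property
    def pinv(self) -> np.ndarray:
        return np.linalg.pinv(self.matrix)

    @cached_property
    def rowspace_projector(self) -> np.ndarray:
        """Projector X^+ X onto the row space; c is estimable iff Pc = c."""
        return self.pinv @ self.matrix

    def _aliasing_report(self) -> list[str]:
        _, r, piv = scipy.linalg.qr(self.matrix, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.matrix.shape) * np.finfo(float).eps if diag.size else 0.0
        kept = diag > tol
        dropped = [self.labels[piv[i]] for i in range(len(piv)) if i >= kept.sum()]
        return sorted(dropped)

    def treatment_contrast(self, level_a: str, level_b: str) -> tuple[np.ndarray, bool]:
        """Contrast vector for tau_a - tau_b and whether it is estimable."""
        for lvl in (level_a, level_b):
            if lvl not in self.treatment_levels:
                raise KeyError(f"unknown treatment level {lvl!r}")
        c = np.zeros(self.n_columns)
        if level_a in self._treatment_cols:
            c[self._treatment_cols[level_a]] = 1.0
        if level_b in self._treatment_cols:
            c[self._treatment_cols[level_b]] -= 1.0
        resid = self.rowspace_projector @ c - c
        estimable = bool(np.linalg.norm(resid, np.inf) < 1e-8 * (1.0 + np.linalg.norm(c)))
        return c, estimable

    def treatment_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.treatment_levels, 2))


def build_design_matrix(design: HybridizationDesign, spec: ModelSpec) -> DesignMatrixBundle:
    """Construct the channels x parameters model matrix for ``spec``.

    Raises ``ValueError`` if the treatment factor adds no dimension beyond
    the nuisance terms (treatment not estimable).
    """
    rows = design.rows
    n = len(rows)
    treatments = design.treatments
    units = design.units
    arrays = design.arrays

    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["(Intercept)"]
    treatment_cols: dict[str, int] = {}
    for lvl in treatments[1:]:
        treatment_cols[lvl] = len(cols)
        cols.append(np.array([1.0 if r.treatment == lvl else 0.0 for r in rows]))
        labels.append(f"treatment[{lvl}]")
    if spec.include_unit:
        for lvl in units[1:]:
            cols.append(np.array([1.0 if r.unit == lvl else 0.0 for r in rows]))
            labels.append(f"unit[{lvl}]")
    array_cols: dict[str, int] = {}
    if spec.include_array:
        for a in arrays:
            array_cols[a] = len(cols)
            cols.append(np.array([1.0 if r.channel.array_id == a else 0.0 for r in rows]))
            labels.append(f"array[{a}]")

    X = np.column_stack(cols)
    bundle = DesignMatrixBundle(
        X, labels, design.channels, treatments, treatment_cols, array_cols, spec
    )

    if len(treatments) > 1:
        keep = [i for i in range(X.shape[1]) if i not in treatment_cols.values()]
        rank_without = int(np.linalg.matrix_rank(X[:, keep]))
        if rank_without == bundle.rank:
            raise ValueError("treatment not estimable: fully aliased with nuisance terms")
    if bundle.aliased:
        logger.info("design matrix (%s): aliased columns dropped: %s",
                    spec.name, ", ".join(bundle.aliased))
    return bundle


@dataclass
class GeneFit:
    """Least-squares fit of one probe under one model."""

    coefficients: np.ndarray
    labels: list[str]
    fitted: np.ndarray
    rss: float
    df_resid: int
    n: int
    rank: int
    loglik: float
    bic: float
    m_values: dict[tuple[str, str], float] = field(default_factory=dict)
    f_stat: float | None = None
    p_value: float | None = None
    exact_fit: bool = False
    saturated: bool = False


def _gaussian_profile_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    """Max Gaussian log-likelihood with sigma-hat^2 = RSS/n (profiled out)."""
    sigma2 = np.maximum(np.asarray(rss, dtype=float) / n, np.finfo(float).tiny)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_gene(y: np.ndarray, bundle: DesignMatrixBundle) -> GeneFit:
    """Fit one probe's channel vector by (pseudo-inverse) least squares.

    A saturated fit (zero residual degrees of freedom) is returned with the
    ``saturated`` flag rather than raising; its p-value stays undefined.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (bundle.n_channels,):
        raise ValueError(f"y has shape {y.shape}, expected ({bundle.n_channels},)")
    beta = bundle.pinv @ y
    fitted = bundle.matrix @ beta
    rss = float(np.sum((y - fitted) ** 2))
    n = bundle.n_channels
    df_resid = n - bundle.rank
    loglik = float(_gaussian_profile_loglik(rss, n))
    bic = -2.0 * loglik + (bundle.rank + 1) * np.log(n)
    m_values = {}
    for a, b in bundle.treatment_pairs():
        c, estimable = bundle.treatment_contrast(a, b)
        m_values[(a, b)] = float(c @ beta) if estimable else float("nan")
    return GeneFit(
        coefficients=beta,
        labels=bundle.labels,
        fitted=fitted,
        rss=rss,
        df_resid=df_resid,
        n=n,
        rank=bundle.rank,
        loglik=loglik,
        bic=bic,
        m_values=m_values,
        saturated=(df_resid == 0),
    )


def f_test_treatment(fit_full: GeneFit, fit_reduced: GeneFit) -> tuple[float, float]:
    """Extra-sum-of-squares F-test for the treatment factor.

    ``fit_reduced`` must be the same probe refit without the treatment
    columns.  An exact full fit (RSS = 0 with reduced RSS > 0) reports
    p = 0; a probe that both models fit exactly (e.g. a constant vector)
    reports F = 0, p = 1.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("full and reduced fits use different sample sizes")
    q = fit_reduced.df_resid - fit_full.df_resid
    if q <= 0:
        raise ValueError("reduced model must have more residual df than the full model")
    if fit_full.df_resid == 0:
        return float("nan"), float("nan")
    scale = max(1.0, fit_reduced.rss)
    if fit_full.rss < _RSS_ATOL * scale:
        if fit_reduced.rss - fit_full.rss < _RSS_ATOL * scale:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ((fit_reduced.rss - fit_full.rss) / q) / (fit_full.rss / fit_full.df_resid)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, q, fit_full.df_resid))
    return float(f), p


def bic_compare(fit_ratio: GeneFit, fit_intensity: GeneFit) -> str:
    """Return the preferred model name (lower BIC; ties go to intensity)."""
    if fit_ratio.n != fit_intensity.n:
        raise ValueError("fits compare different numbers of channels")
    return MODEL_RATIO if fit_ratio.bic < fit_intensity.bic else MODEL_INTENSITY


@dataclass
class ResultTable:
    """Per-probe results of one dataset under one model.

    ``frame`` is indexed by probe_id with columns ``F``, ``p``,
    ``neg_log10_p``, ``bic``, ``df_resid``, ``sigma2`` (unbiased residual
    variance RSS/df), ``rank``, one ``M[a-b]`` column per treatment pair,
    and ``mean_abs_array_effect`` for ratio-model fits.
    """

    frame: pd.DataFrame
    model: str

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate probe ids in result table")

    @property
    def probe_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def ranking(self) -> np.ndarray:
        """Probe ids ordered by ascending p; ties broken by probe_id."""
        tmp = self.frame.assign(_probe=self.frame.index.astype(str))
        tmp = tmp.sort_values(["p", "_probe"], kind="mergesort")
        return tmp.index.to_numpy()

    def m_column(self, group_a: str, group_b: str) -> pd.Series:
        """Signed M-values for the contrast group_a - group_b."""
        name = f"M[{group_a}-{group_b}]"
        if name in self.frame.columns:
            return self.frame[name]
        rev = f"M[{group_b}-{group_a}]"
        if rev in self.frame.columns:
            return -self.frame[rev]
        raise KeyError(f"no M-value column for contrast {group_a} vs {group_b}")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model: {self.model}\n")
            self.frame.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ResultTable":
        model = MODEL_INTENSITY
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# model:"):
                model = first.split(":", 1)[1].strip()
                frame = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(frame=frame, model=model)


def fit_dataset(
    m: ExpressionMatrix,
    design: HybridizationDesign,
    spec: ModelSpec,
) -> ResultTable:
    """Fit every probe under ``spec`` and test the treatment factor.

    The design may contain more channels than the matrix; it is subset to
    the matrix's channels first.  Fitting is vectorized across probes (the
    model matrix is probe-independent), matching :func:`fit_gene` probe by
    probe.
    """
    if not m.log2:
        raise ValueError("fit_dataset expects log2-scale data")
    sub = design.subset(m.channels)
    if sub.channels != m.channels:
        m = m.subset_channels(sub.channels)  # align columns to design row order

    bundle = build_design_matrix(sub, spec)
    reduced = _reduced_bundle(sub, spec)

    Y = m.values  # probes x channels
    n = bundle.n_channels
    B = Y @ bundle.pinv.T
    resid = Y - B @ bundle.matrix.T
    rss_f = np.einsum("ij,ij->i", resid, resid)
    B_r = Y @ reduced.pinv.T
    resid_r = Y - B_r @ reduced.matrix.T
    rss_r = np.einsum("ij,ij->i", resid_r, resid_r)

    df_f = n - bundle.rank
    df_r = n - reduced.rank
    q = df_r - df_f
    if q <= 0:
        raise ValueError("treatment not estimable: no degrees of freedom for the F-test")

    scale = np.maximum(1.0, rss_r)
    exact = rss_f < _RSS_ATOL * scale
    both_exact = exact & ((rss_r - rss_f) < _RSS_ATOL * scale)

    if df_f > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((rss_r - rss_f) / q) / (rss_f / df_f)
        f_stat = np.clip(f_stat, 0.0, np.inf)
        p = stats.f.sf(f_stat, q, df_f)
        f_stat = np.where(exact, np.inf, f_stat)
        p = np.where(exact, 0.0, p)
        f_stat = np.where(both_exact, 0.0, f_stat)
        p = np.where(both_exact, 1.0, p)
        sigma2 = rss_f / df_f
    else:
        f_stat = np.full(len(Y), np.nan)
        p = np.full(len(Y), np.nan)
        sigma2 = np.full(len(Y), np.nan)

    loglik = _gaussian_profile_loglik(rss_f, n)
    bic = -2.0 * loglik + (bundle.rank + 1) * np.log(n)

    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)

    data = {
        "F": f_stat,
        "p": p,
        "neg_log10_p": neg_log10_p,
        "bic": bic,
        "df_resid": np.full(len(Y), df_f),
        "sigma2": sigma2,
        "rank": np.full(len(Y), bundle.rank),
        "rss": rss_f,
    }
    for a, b in bundle.treatment_pairs():
        c, estimable = bundle.treatment_contrast(a, b)
        data[f"M[{a}-{b}]"] = B @ c if estimable else np.full(len(Y), np.nan)
    if spec.include_array and bundle.array_cols:
        # center the indicator coefficients: deviations from the mean array
        # level are estimable and invariant to the coding's redundancy
        idx = list(bundle.array_cols.values())
        alphas = B[:, idx]
        centered = alphas - alphas.mean(axis=1, keepdims=True)
        data["mean_abs_array_effect"] = np.abs(centered).mean(axis=1)

    frame = pd.DataFrame(data, index=pd.Index(m.probe_ids, name="probe_id"))
    logger.info("fit_dataset(%s): %d probes, %d channels, rank %d, df %d",
                spec.name, len(Y), n, bundle.rank, df_f)
    return ResultTable(frame=frame, model=spec.name)


def _reduced_bundle(design: HybridizationDesign, spec: ModelSpec) -> DesignMatrixBundle:
    """Model matrix without the treatment columns (for the F-test)."""
    full = build_design_matrix(design, spec)
    keep = [i for i in range(full.n_columns) if i not in full._treatment_cols.values()]
    matrix = full.matrix[:, keep]
    labels = [full.labels[i] for i in keep]
    array_cols = {a: keep.index(i) for a, i in full.array_cols.items() if i in keep}
    return DesignMatrixBundle(
        matrix, labels, full.channels, full.treatment_levels, {}, array_cols, spec
    )


def bic_preference(rt_ratio: ResultTable, rt_intensity: ResultTable) -> tuple[float, pd.Series]:
    """Per-probe BIC model choice and the fraction preferring intensity.

    Ties go to the intensity model (fewer parameters).
    """
    if not rt_ratio.frame.index.equals(rt_intensity.frame.index):
        raise ValueError("result tables cover different probes")
    choice = pd.Series(
        np.where(rt_ratio.frame["bic"] < rt_intensity.frame["bic"], MODEL_RATIO, MODEL_INTENSITY),
        index=rt_ratio.frame.index,
        name="preferred_model",
    )
    frac_intensity = float((choice == MODEL_INTENSITY).mean())
    return frac_intensity, choice
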