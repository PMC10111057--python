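"""Statistical evaluation of therapy effect, correlation screen, summaries.

The before/after comparison of a therapy group takes the 16 per-channel AUC
values of each session as two paired samples.  Normality is first checked
with the D'Agostino-Pearson omnibus K-squared test (pooled over both
sessions by default); the location comparison is the Wilcoxon signed-rank
test, exact for n <= 25, with the rank-sum form available behind a flag for
literal replication.  Zero differences are dropped (Wilcoxon's original
treatment).  The null hypothesis S0 = Sf is rejected when p < 0.05; no
multiple-testing correction is applied across groups, mirroring the study
design.

The correlation screen rank-correlates (Spearman by default) demographic and
audiological variables -- age, sex, laterality, tinnitus pitch and intensity,
per-ear hearing loss, heart rate, therapy -- with the AUC summary measures
(AUCmax magnitude and AUCch topography).  Categorical variables are integer
coded: sex F=0/M=1, laterality L=0/R=1/B=2, therapy by group order, AUCch by
montage index.

Questionnaire effects per group and instrument are the percentages of
participants whose THI/HADS *category* decreased (positive), stayed (none)
or increased (negative) between sessions, rounded to integer percent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (GROUPS, Participant, categorize_effect, categorize_hads,
                     categorize_thi)
from .exceptions import (DegenerateDataError, InsufficientSampleError,
                         MissingDataError)
from .montage import MONTAGE_16

__all__ = [
    "TherapyTestResult",
    "CorrelationScreen",
    "dagostino_pearson",
    "wilcoxon_paired",
    "evaluate_therapy",
    "correlation_screen",
    "participant_table",
    "effect_summary",
    "build_report",
]

ALPHA = 0.05


@dataclass
class TherapyTestResult:
    """Outcome of the S0-vs-Sf evaluation for one therapy group."""

    group: str
    normality_p: float
    p_value: float
    decision: str                 # "difference" | "no difference"
    alpha: float = ALPHA
    test: str = "signed-rank"


@dataclass
class CorrelationScreen:
    """Pairwise rank-correlation matrix with significance flags."""

    rho: pd.DataFrame
    pval: pd.DataFrame
    significant: pd.DataFrame
    undefined: list[str] = field(default_factory=list)
    method: str = "spearman"


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def dagostino_pearson(x: np.ndarray) -> float:
    """D'Agostino-Pearson omnibus normality p-value (K^2 vs chi^2, 2 df)."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise InsufficientSampleError(
            f"D'Agostino-Pearson needs n >= 8, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: normality undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(x)
    return float(p)


def wilcoxon_paired(auc_s0: np.ndarray, auc_sf: np.ndarray,
                    alternative: str = "two-sided",
                    form: str = "signed-rank") -> float:
    """Paired nonparametric comparison of the two sessions' channel AUCs.

    ``signed-rank`` (default): Wilcoxon signed-rank on the paired
    differences, exact null distribution for n <= 25, zeros dropped.
    ``rank-sum``: the unpaired rank-sum form, for literal replication.
    """
    a, b = np.asarray(auc_s0, dtype=float), np.asarray(auc_sf, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sessions must pair channel for channel")
    if form == "rank-sum":
        return float(sps.ranksums(b, a, alternative=alternative).pvalue)
    if form != "signed-rank":
        raise ValueError(f"unknown test form {form!r}")
    d = b - a
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 else "auto"
    res = sps.wilcoxon(b, a, zero_method="wilcox", alternative=alternative,
                       method=method)
    return float(res.pvalue)


def evaluate_therapy(auc_s0: np.ndarray, auc_sf: np.ndarray, group: str = "",
                     alpha: float = ALPHA, normality: str = "pooled",
                     form: str = "signed-rank") -> TherapyTestResult:
    """Normality check, then the paired nonparametric comparison.

    ``normality='pooled'`` tests the 32 pooled AUC values; ``'per-session'``
    tests each session separately and reports the smaller p.  The decision is
    "difference" iff the comparison p-value is below ``alpha``.
    """
    if auc_s0 is None or auc_sf is None:
        raise MissingDataError("both sessions are required")
    a, b = np.asarray(auc_s0, dtype=float), np.asarray(auc_sf, dtype=float)
    if normality == "pooled":
        norm_p = dagostino_pearson(np.concatenate([a, b]))
    elif normality == "per-session":
        norm_p = min(dagostino_pearson(a), dagostino_pearson(b))
    else:
        raise ValueError(f"unknown normality mode {normality!r}")
    p = wilcoxon_paired(a, b, form=form)
    decision = "difference" if p < alpha else "no difference"
    return TherapyTestResult(group=group, normality_p=norm_p, p_value=p,
                             decision=decision, alpha=alpha, test=form)


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

_SEX_CODE = {"F": 0, "M": 1}
_LATERALITY_CODE = {"L": 0, "R": 1, "B": 2}


def _encode(series: pd.Series) -> pd.Series:
    if series.dtype.kind in "ifu":
        return series.astype(float)
    name = series.name or ""
    if name == "sex":
        return series.map(_SEX_CODE).astype(float)
    if name == "laterality":
        return series.map(_LATERALITY_CODE).astype(float)
    if name in ("group", "therapy"):
        return series.map({g: i for i, g in enumerate(GROUPS)}).astype(float)
    if name in ("aucch", "auc_channel"):
        return series.map({ch: i for i, ch in enumerate(MONTAGE_16)}).astype(float)
    raise ValueError(f"no documented coding for categorical column {name!r}")


def correlation_screen(table: pd.DataFrame, method: str = "spearman",
                       alpha: float = ALPHA) -> CorrelationScreen:
    """Pairwise correlations among participant variables, flagged at alpha.

    Pairs are computed on complete rows (pairwise deletion) and need at
    least 3; constant columns yield undefined (NaN) coefficients and are
    listed in ``undefined``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    enc = pd.DataFrame({c: _encode(table[c]) for c in table.columns})
    cols = list(enc.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    undefined = [c for c in cols if enc[c].dropna().nunique() <= 1]
    fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i in range(k):
        for j in range(i + 1, k):
            sub = enc[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or cols[i] in undefined or cols[j] in undefined:
                r, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = fn(sub[cols[i]], sub[cols[j]])
                    r, p = float(res.statistic), float(res.pvalue)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    pval_df = pd.DataFrame(pval, index=cols, columns=cols)
    sig = (pval_df < alpha) & np.isfinite(rho_df)
    np.fill_diagonal(sig.values, False)
    return CorrelationScreen(rho=rho_df, pval=pval_df, significant=sig,
                             undefined=undefined, method=method)


def participant_table(cohort: list[Participant],
                      auc_results: dict[str, tuple[float, str]] | None = None,
                      ) -> pd.DataFrame:
    """Participant-by-variable matrix for the correlation screen.

    ``auc_results`` optionally maps participant id -> (AUCmax, AUCch).
    Healthy participants (no tinnitus) contribute NaN tinnitus fields.
    """
    rows = []
    for p in cohort:
        row = {
            "age": p.age,
            "sex": p.sex,
            "heart_rate": p.heart_rate,
            "hl_left": p.audiogram.pta("left"),
            "hl_right": p.audiogram.pta("right"),
            "laterality": p.tinnitus.laterality if p.tinnitus else None,
            "tinnitus_pitch": p.tinnitus.pitch if p.tinnitus else np.nan,
            "tinnitus_intensity": p.tinnitus.intensity if p.tinnitus else np.nan,
            "therapy": p.group,
        }
        if auc_results and p.id in auc_results:
            row["aucmax"], row["aucch"] = auc_results[p.id]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# questionnaire effect summary
# ---------------------------------------------------------------------------

def _instrument_categories(p: Participant, instrument: str) -> tuple[str, str] | None:
    if instrument == "THI":
        if p.thi_score is None:
            return None
        return categorize_thi(p.thi_score["S0"]), categorize_thi(p.thi_score["Sf"])
    scores = p.hads_anxiety if instrument == "HADS-A" else p.hads_stress
    return categorize_hads(scores["S0"]), categorize_hads(scores["Sf"])


def effect_summary(cohort: list[Participant]) -> pd.DataFrame:
    """Percent positive / none / negative per group and instrument.

    Percentages are over the number of scored participants in the group and
    rounded to integer percent (so a triple can sum to 100 +- 1).
    """
    rows = []
    for g in GROUPS:
        members = [p for p in cohort if p.group == g]
        if not members:
            warnings.warn(f"group {g!r} is empty; excluded from the summary",
                          RuntimeWarning, stacklevel=2)
            continue
        for instrument in ("THI", "HADS-A", "HADS-S"):
            counts = {"positive": 0, "none": 0, "negative": 0}
            n = 0
            for p in members:
                cats = _instrument_categories(p, instrument)
                if cats is None:
                    continue
                counts[categorize_effect(instrument, *cats).label] += 1
                n += 1
            if n == 0:
                continue
            rows.append({
                "group": g, "instrument": instrument, "n": n,
                "positive_pct": round(100.0 * counts["positive"] / n),
                "none_pct": round(100.0 * counts["none"] / n),
                "negative_pct": round(100.0 * counts["negative"] / n),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def build_report(therapy_tests: list[TherapyTestResult],
                 auc_comparisons: list | None = None,
                 effects: pd.DataFrame | None = None,
                 screen: CorrelationScreen | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Assemble a machine-readable results bundle (deterministic).

    Returns the bundle as a dict; when ``out_dir`` is given also writes
    ``report.json``, ``therapy_tests.csv`` and ``summary.txt`` there.
    Byte-identical output for identical inputs.
    """
    if not therapy_tests:
        raise ValueError("report needs at least one evaluated group")
    bundle: dict = {
        "therapy_tests": [
            {"group": t.group, "normality_p": round(t.normality_p, 6),
             "p_value": round(t.p_value, 6), "decision": t.decision,
             "alpha": t.alpha, "test": t.test}
            for t in therapy_tests
        ],
    }
    if auc_comparisons:
        bundle["auc"] = [
            {"group": c.group, "auc_max": round(c.auc_max, 4),
             "auc_channel": c.auc_channel,
             "auc_per_channel": {ch: round(float(v), 4)
                                 for ch, v in zip(c.channels, c.auc)}}
            for c in auc_comparisons
        ]
    if effects is not None and len(effects):
        bundle["questionnaire_effects"] = effects.to_dict(orient="records")
    if screen is not None:
        bundle["correlations"] = {
            "method": screen.method,
            "significant_pairs": [
                {"pair": [a, b], "rho": round(float(screen.rho.loc[a, b]), 4),
                 "p": round(float(screen.pval.loc[a, b]), 6)}
                for i, a in enumerate(screen.rho.index)
                for b in screen.rho.columns[i + 1:]
                if bool(screen.significant.loc[a, b])
            ],
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        pd.DataFrame(bundle["therapy_tests"]).to_csv(out / "therapy_tests.csv",
                                                     index=False)
        lines = ["Therapy evaluation (S0 vs Sf, alpha = 0.05)", ""]
        for t in therapy_tests:
            lines.append(f"  {t.group:8s} p = {t.p_value:.4f} -> {t.decision}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return bundle
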