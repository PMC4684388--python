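"""Randomized complete block design ANOVA and LSD mean comparison.

The four estimation methods are the treatments; each sampled tree is a
block (every method predicts every tree, so the design is complete and
balanced with one observation per cell).  The standard additive two-way
decomposition without replication gives

    SS_total = SS_treatment + SS_block + SS_error

with F = MS_treatment / MS_error on (t−1, (t−1)(b−1)) degrees of
freedom.  After a significant F-test, pairs of treatment means are
compared against the least significant difference

    LSD = t_{1−α/2, df_error} * sqrt(2 MS_error / b)

and letter groups are assigned so that two treatments share a letter
exactly when their means do not differ by more than the LSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaTable", "LsdGrouping", "rcbd_anova", "lsd_compare", "compare_methods"]


@dataclass(frozen=True)
class AnovaTable:
    """Two-way RCBD decomposition with F tests for treatment and block."""

    ss_treatment: float
    ss_block: float
    ss_error: float
    df_treatment: int
    df_block: int
    df_error: int
    f_treatment: float
    p_treatment: float
    f_block: float
    p_block: float
    alpha: float
    n_blocks: int
    n_treatments: int

    @property
    def ms_treatment(self) -> float:
        return self.ss_treatment / self.df_treatment

    @property
    def ms_block(self) -> float:
        return self.ss_block / self.df_block

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def ss_total(self) -> float:
        return self.ss_treatment + self.ss_block + self.ss_error

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sum_sq": [self.ss_treatment, self.ss_block, self.ss_error],
                "df": [self.df_treatment, self.df_block, self.df_error],
                "mean_sq": [self.ms_treatment, self.ms_block, self.ms_error],
                "F": [self.f_treatment, self.f_block, np.nan],
                "p_value": [self.p_treatment, self.p_block, np.nan],
            },
            index=["treatment", "block", "error"],
        )


@dataclass(frozen=True)
class LsdGrouping:
    """Treatment means with LSD letter groups (shared letter = not different)."""

    treatments: tuple
    means: tuple
    letters: tuple  # one string of letters per treatment
    lsd: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "letters": self.letters}, index=list(self.treatments)
        )


def rcbd_anova(errors, alpha: float = 0.05) -> AnovaTable:
    """RCBD ANOVA of a complete blocks × treatments response matrix.

    ``errors`` is an (b, t) array or DataFrame: rows are blocks (trees),
    columns treatments (methods).  Missing cells are an error — the
    design requires completeness.
    """
    if isinstance(errors, pd.DataFrame):
        mat = errors.to_numpy(dtype=float)
    else:
        mat = np.asarray(errors, dtype=float)
    if mat.ndim != 2:
        raise ValueError("errors must be a 2-d blocks × treatments matrix")
    if np.isnan(mat).any():
        raise ValueError("RCBD requires a complete matrix; found missing cells")
    b, t = mat.shape
    if b < 2 or t < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    grand = mat.mean()
    treat_means = mat.mean(axis=0)
    block_means = mat.mean(axis=1)
    ss_treat = b * float(((treat_means - grand) ** 2).sum())
    ss_block = t * float(((block_means - grand) ** 2).sum())
    ss_total = float(((mat - grand) ** 2).sum())
    ss_error = ss_total - ss_treat - ss_block
    ss_error = max(ss_error, 0.0)  # guard tiny negative round-off
    df_t, df_b = t - 1, b - 1
    df_e = df_t * df_b
    ms_e = ss_error / df_e
    if ms_e > 0:
        f_t = (ss_treat / df_t) / ms_e
        f_b = (ss_block / df_b) / ms_e
        p_t = float(stats.f.sf(f_t, df_t, df_e))
        p_b = float(stats.f.sf(f_b, df_b, df_e))
    else:
        f_t = 0.0 if ss_treat == 0 else np.inf
        f_b = 0.0 if ss_block == 0 else np.inf
        p_t = 1.0 if ss_treat == 0 else 0.0
        p_b = 1.0 if ss_block == 0 else 0.0
    return AnovaTable(
        ss_treatment=ss_treat, ss_block=ss_block, ss_error=ss_error,
        df_treatment=df_t, df_block=df_b, df_error=df_e,
        f_treatment=float(f_t), p_treatment=p_t,
        f_block=float(f_b), p_block=p_b,
        alpha=alpha, n_blocks=b, n_treatments=t,
    )


def _assign_letters(means_sorted, lsd):
    """Letters by the sorted-means insertion scheme.

    Means are sorted descending; every maximal contiguous run whose
    extremes differ by at most the LSD gets one letter.  A difference
    of exactly the LSD counts as not significant.
    """
    t = len(means_sorted)
    ranges = []
    for i in range(t):
        j = i
        while j + 1 < t and means_sorted[i] - means_sorted[j + 1] <= lsd:
            j += 1
        ranges.append((i, j))
    maximal = [r for r in ranges if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in ranges)]
    # deduplicate while preserving order
    seen, runs = set(), []
    for r in maximal:
        if r not in seen:
            seen.add(r)
            runs.append(r)
    letters_sorted = ["" for _ in range(t)]
    for letter_idx, (i, j) in enumerate(runs):
        ch = chr(ord("A") + letter_idx)
        for s in range(i, j + 1):
            letters_sorted[s] += ch
    return letters_sorted


def lsd_compare(anova: AnovaTable, means, treatments=None, alpha: float | None = None) -> LsdGrouping:
    """LSD multiple comparison of treatment means after an RCBD ANOVA.

    ``means`` are the treatment means in the column order of the ANOVA
    matrix; ``treatments`` optional labels.  Two treatments share a
    letter iff their means differ by at most the LSD threshold.
    """
    if anova.df_error <= 0:
        raise ValueError("no error degrees of freedom for the LSD")
    alpha = anova.alpha if alpha is None else alpha
    means = np.asarray(means, dtype=float)
    if means.size != anova.n_treatments:
        raise ValueError("one mean per treatment is required")
    if treatments is None:
        treatments = tuple(f"T{i + 1}" for i in range(means.size))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, anova.df_error)
    lsd = float(tcrit * np.sqrt(2.0 * anova.ms_error / anova.n_blocks))
    order = np.argsort(-means, kind="stable")
    letters_sorted = _assign_letters(means[order], lsd)
    letters = [""] * means.size
    for pos, orig in enumerate(order):
        letters[orig] = letters_sorted[pos]
    return LsdGrouping(
        treatments=tuple(treatments), means=tuple(float(m) for m in means),
        letters=tuple(letters), lsd=lsd, alpha=alpha,
    )


def compare_methods(matrix: pd.DataFrame, component: str, response: str = "absolute",
                    alpha: float = 0.05) -> tuple[AnovaTable, LsdGrouping]:
    """RCBD ANOVA + LSD of per-tree carbon prediction errors for one component.

    ``matrix`` is the tidy method-error frame (see
    :func:`allocarbon.carbon.method_error_matrix`); ``response`` selects
    absolute errors (default — magnitude differences are the question of
    interest) or signed errors.
    """
    if response not in ("absolute", "signed"):
        raise ValueError("response must be 'absolute' or 'signed'")
    sl = matrix[matrix["component"] == component]
    if sl.empty:
        raise ValueError(f"no entries for component {component!r}")
    wide = sl.pivot(index="tree", columns="method", values="error_kg").sort_index(axis=1)
    if response == "absolute":
        wide = wide.abs()
    anova = rcbd_anova(wide, alpha=alpha)
    means = wide.mean(axis=0).to_numpy()
    grouping = lsd_compare(anova, means, treatments=tuple(f"method_{m}" for m in wide.columns))
    return anova, grouping
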