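"""Empirical-Bayes calibration of alignment scores to fold-membership posteriors.

Each structural-alignment method emits raw pairwise scores on its own scale
(Z-scores, -ln p, TM-scores, elastic distances ...).  To compare methods on
a common footing, every score is converted to the posterior probability
that the two aligned domains belong to the same fold given that their
similarity exceeds the observed value:

    P(F=1 | S > s) = P(S > s | F=1) P(F=1)
                     ---------------------------------------------
                     P(S > s | F=1) P(F=1) + P(S > s | F=0) P(F=0)

Priors are the observed proportions of fold-sibling versus unrelated pairs;
the conditionals are the empirical survival proportions of each population.
No smoothing is applied — the estimates are pure counting.

Following the practice of computing significance for all-alpha domains
separately, pairs are partitioned into ``alpha_involved`` (at least one
all-alpha domain) and ``other``, and each partition is calibrated on its
own.  Posterior levels are inverted back to effective score cutoffs, which
for distance-oriented scores are *upper* limits.

The stage is exposed in a model/results idiom: :class:`BridgeCalibration`
is built from a score table and annotation, ``fit()`` performs the counting
and returns a :class:`CalibrationResult` carrying the per-partition
calibrations, threshold tables and a text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class ScoreTable:
    """Sparse symmetric pairwise scores for one alignment method.

    ``frame`` holds one row per unordered domain pair (columns ``domain_i``,
    ``domain_j`` plus one or more score columns).  ``orientation`` declares
    whether greater raw scores mean more similar (``"similarity"``) or less
    (``"distance"``); all internal arithmetic flips distance scores so that
    "greater is more similar" holds everywhere downstream.
    """

    frame: pd.DataFrame
    method: str
    orientation: str = "similarity"
    score_columns: list[str] = field(default_factory=lambda: ["score"])

    def __post_init__(self):
        if self.orientation not in ("similarity", "distance"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for col in ("domain_i", "domain_j", *self.score_columns):
            if col not in self.frame.columns:
                raise ValueError(f"score table for {self.method!r} lacks column {col!r}")
        if (self.frame["domain_i"] == self.frame["domain_j"]).any():
            raise ValueError("score table contains self-pairs")
        key = self._pair_key()
        if key.duplicated().any():
            raise ValueError("score table contains duplicate (or mirrored) pairs")

    def _pair_key(self) -> pd.Series:
        a = self.frame["domain_i"].astype(str)
        b = self.frame["domain_j"].astype(str)
        return a.where(a < b, b) + "\t" + b.where(a < b, a)

    @property
    def sign(self) -> float:
        """Multiplier turning raw scores into similarity orientation."""
        return -1.0 if self.orientation == "distance" else 1.0

    def oriented(self, column: str | None = None) -> np.ndarray:
        """Scores with distance orientation sign-flipped (greater = more similar)."""
        col = column if column is not None else self.score_columns[0]
        return self.sign * self.frame[col].to_numpy(dtype=float)


def select_score_by_auc(
    table: ScoreTable, is_sibling: np.ndarray
) -> tuple[str, float]:
    """Pick the score column that best discriminates fold siblings.

    The AUROC of sibling-versus-unrelated discrimination is computed for
    every candidate column (after orienting distance scores) and the
    maximising column is returned with its AUROC.  Ties are broken by the
    declared column order.  A constant column scores 0.5 with a warning.
    """
    is_sibling = np.asarray(is_sibling, dtype=bool)
    if is_sibling.shape[0] != len(table.frame):
        raise ValueError("sibling labels do not match the score table length")
    best: tuple[str, float] | None = None
    for col in table.score_columns:
        scores = table.oriented(col)
        auc = _auroc(scores[is_sibling], scores[~is_sibling])
        if best is None or auc > best[1]:
            best = (col, auc)
    assert best is not None
    return best


def _auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUROC by concordant-pair counting (ties credited one half)."""
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both sibling and unrelated scores are required")
    if np.ptp(np.concatenate([pos, neg])) == 0.0:
        warnings.warn("score column has no variance; AUROC is 0.5", stacklevel=3)
        return 0.5
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


class EmpiricalCalibration:
    """Survival-proportion calibration for one pair partition.

    Holds the sorted (similarity-oriented) sibling and unrelated score
    samples, the partition priors, and evaluates the posterior
    P(F=1 | S > s) at arbitrary scores.  Strict inequality is used in the
    survival proportions; at scores at or beyond the joint maximum (where
    both strict survivals vanish) the evaluation falls back to ``>=``
    counting so the top-scoring alignment is still assigned a posterior.
    """

    def __init__(
        self,
        sibling_scores: np.ndarray,
        unrelated_scores: np.ndarray,
        method: str = "",
        partition: str = "other",
        orientation: str = "similarity",
    ):
        sib = np.sort(np.asarray(sibling_scores, dtype=float))
        unrel = np.sort(np.asarray(unrelated_scores, dtype=float))
        if sib.size == 0:
            raise ValueError(
                f"partition {partition!r} has no fold-sibling pairs; posterior undefined"
            )
        if unrel.size == 0:
            raise ValueError(
                f"partition {partition!r} has no unrelated pairs; posterior undefined"
            )
        self._sib = sib
        self._unrel = unrel
        self.method = method
        self.partition = partition
        self.orientation = orientation
        total = sib.size + unrel.size
        self.prior_same_fold = sib.size / total
        self.prior_diff_fold = unrel.size / total

    # -- empirical survival functions ------------------------------------

    def survival_same(self, s) -> np.ndarray:
        """P(S > s | F = 1), empirical proportion."""
        s = np.asarray(s, dtype=float)
        return (self._sib.size - np.searchsorted(self._sib, s, side="right")) / self._sib.size

    def survival_diff(self, s) -> np.ndarray:
        """P(S > s | F = 0), empirical proportion."""
        s = np.asarray(s, dtype=float)
        return (self._unrel.size - np.searchsorted(self._unrel, s, side="right")) / self._unrel.size

    def posterior(self, s) -> np.ndarray:
        """Posterior P(F=1 | S > s) at similarity-oriented score(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        sf1 = self.survival_same(s)
        sf0 = self.survival_diff(s)
        num = sf1 * self.prior_same_fold
        den = num + sf0 * self.prior_diff_fold
        out = np.full(s.shape, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if (~ok).any():
            # beyond the joint support: count with >= instead of >
            ge1 = (self._sib.size - np.searchsorted(self._sib, s[~ok], side="left")) / self._sib.size
            ge0 = (self._unrel.size - np.searchsorted(self._unrel, s[~ok], side="left")) / self._unrel.size
            num2 = ge1 * self.prior_same_fold
            den2 = num2 + ge0 * self.prior_diff_fold
            out[~ok] = np.where(den2 > 0, num2 / np.where(den2 > 0, den2, 1.0), np.nan)
        below = s < min(self._sib[0], self._unrel[0])
        if below.any():
            warnings.warn(
                "scores below the observed support; posterior evaluated at the "
                "leftmost estimable point",
                stacklevel=2,
            )
        return out

    @property
    def support(self) -> tuple[float, float]:
        lo = min(self._sib[0], self._unrel[0])
        hi = max(self._sib[-1], self._unrel[-1])
        return float(lo), float(hi)

    # -- threshold inversion ---------------------------------------------

    def threshold(self, p: float) -> float | None:
        """Smallest observed score s with posterior(s') >= p for all observed s' >= s.

        The suffix condition keeps the inversion well defined even where the
        raw posterior-versus-score curve is locally non-monotone in sparse
        regions.  Returns the similarity-oriented cutoff, or ``None`` when no
        score attains the level.
        """
        if not 0.0 < p < 1.0:
            raise ValueError("posterior level must be in (0, 1)")
        candidates = np.unique(np.concatenate([self._sib, self._unrel]))
        post = self.posterior(candidates)
        suffix_ok = np.isfinite(post) & (post >= p)
        # walk from the top: the admissible suffix is the maximal run of True
        ok_from_here = np.logical_and.accumulate(suffix_ok[::-1])[::-1]
        hits = np.flatnonzero(ok_from_here)
        if hits.size == 0:
            return None
        return float(candidates[hits[0]])


@dataclass
class CalibrationResult:
    """Fitted calibration for one method: both alpha partitions plus tables."""

    method: str
    orientation: str
    score_column: str
    score_auc: float | None
    partitions: dict[str, EmpiricalCalibration]

    def model_for(self, alpha_involved: bool) -> EmpiricalCalibration:
        return self.partitions["alpha_involved" if alpha_involved else "other"]

    def posterior(self, raw_scores, alpha_involved) -> np.ndarray:
        """Posterior for raw scores, routed to the matching partition model.

        ``raw_scores`` are on the method's native scale; the orientation
        sign-flip is applied here so callers never handle it.
        """
        raw = np.atleast_1d(np.asarray(raw_scores, dtype=float))
        alpha = np.atleast_1d(np.asarray(alpha_involved, dtype=bool))
        if alpha.shape != raw.shape:
            raise ValueError("scores and alpha flags must have matching shapes")
        sign = -1.0 if self.orientation == "distance" else 1.0
        out = np.empty(raw.shape)
        for name, mask in [("alpha_involved", alpha), ("other", ~alpha)]:
            if mask.any():
                if name not in self.partitions:
                    raise ValueError(f"no calibration fitted for partition {name!r}")
                out[mask] = self.partitions[name].posterior(sign * raw[mask])
        return out

    def threshold_table(self, levels=(0.5, 0.6, 0.7, 0.8, 0.9)) -> pd.DataFrame:
        """Effective raw-score cutoffs per partition and posterior level.

        For distance-oriented methods the cutoffs are upper limits (an
        alignment is significant when its distance falls *below* the
        cutoff); the ``limit`` column records the direction and
        ``attainable`` flags levels no observed score reaches.
        """
        sign = -1.0 if self.orientation == "distance" else 1.0
        limit = "upper" if self.orientation == "distance" else "lower"
        rows = []
        for partition, model in self.partitions.items():
            for p in levels:
                cut = model.threshold(p)
                rows.append(
                    {
                        "method": self.method,
                        "score": self.score_column,
                        "partition": partition,
                        "posterior": p,
                        "cutoff": np.nan if cut is None else sign * cut,
                        "limit": limit,
                        "attainable": cut is not None,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, levels=(0.5, 0.6, 0.7, 0.8, 0.9)) -> str:
        lines = [
            f"Bridge calibration: method={self.method} "
            f"score={self.score_column} orientation={self.orientation}",
        ]
        if self.score_auc is not None:
            lines.append(f"  score selected by AUROC = {self.score_auc:.4f}")
        for partition, model in self.partitions.items():
            lines.append(
                f"  [{partition}] n_sibling={model._sib.size} "
                f"n_unrelated={model._unrel.size} "
                f"prior_same_fold={model.prior_same_fold:.6f}"
            )
        table = self.threshold_table(levels)
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class BridgeCalibration:
    """Model object: calibrate one method's scores against fold labels.

    Parameters
    ----------
    table:
        The method's :class:`ScoreTable`.
    is_sibling:
        Boolean array, one entry per table row: the pair shares a fold.
    alpha_involved:
        Boolean array: at least one domain of the pair is all-alpha.
    score_column:
        Which score column to calibrate.  ``None`` selects the AUROC
        maximiser when several columns exist.
    """

    def __init__(
        self,
        table: ScoreTable,
        is_sibling: np.ndarray,
        alpha_involved: np.ndarray,
        score_column: str | None = None,
    ):
        self.table = table
        self.is_sibling = np.asarray(is_sibling, dtype=bool)
        self.alpha_involved = np.asarray(alpha_involved, dtype=bool)
        n = len(table.frame)
        if self.is_sibling.shape != (n,) or self.alpha_involved.shape != (n,):
            raise ValueError("label arrays must match the score table length")
        self.score_column = score_column
        self._selected_auc: float | None = None

    @classmethod
    def from_score_table(
        cls,
        table: ScoreTable,
        annotation: pd.DataFrame,
        alpha_class: str = "a",
        score_column: str | None = None,
    ) -> "BridgeCalibration":
        """Derive sibling/alpha labels from a SCOP-style annotation table."""
        fold = annotation.set_index("domain_id")["fold"]
        cls_of = annotation.set_index("domain_id")["class"]
        fi = table.frame["domain_i"].map(fold)
        fj = table.frame["domain_j"].map(fold)
        if fi.isna().any() or fj.isna().any():
            missing = sorted(
                set(table.frame.loc[fi.isna(), "domain_i"]).union(
                    table.frame.loc[fj.isna(), "domain_j"]
                )
            )
            raise ValueError(f"domains missing from annotation: {missing[:10]}")
        is_sibling = (fi == fj).to_numpy()
        alpha = (
            (table.frame["domain_i"].map(cls_of) == alpha_class)
            | (table.frame["domain_j"].map(cls_of) == alpha_class)
        ).to_numpy()
        return cls(table, is_sibling, alpha, score_column=score_column)

    def fit(self) -> CalibrationResult:
        """Count the survival proportions and return the fitted result."""
        column = self.score_column
        auc: float | None = None
        if column is None:
            if len(self.table.score_columns) > 1:
                column, auc = select_score_by_auc(self.table, self.is_sibling)
            else:
                column = self.table.score_columns[0]
        scores = self.table.oriented(column)
        partitions = {}
        for name, mask in [
            ("alpha_involved", self.alpha_involved),
            ("other", ~self.alpha_involved),
        ]:
            if not mask.any():
                warnings.warn(f"partition {name!r} has no pairs; skipped")
                continue
            partitions[name] = EmpiricalCalibration(
                scores[mask & self.is_sibling],
                scores[mask & ~self.is_sibling],
                method=self.table.method,
                partition=name,
                orientation=self.table.orientation,
            )
        return CalibrationResult(
            method=self.table.method,
            orientation=self.table.orientation,
            score_column=column,
            score_auc=auc,
            partitions=partitions,
        )


def analytic_cutoff(sibling_dist, unrelated_dist, prior_same: float, p: float) -> float:
    """Closed-form score cutoff for a known sibling/unrelated score mixture.

    Solves P(F=1 | S > s) = p for continuous distributions with ``.sf``
    survival functions (e.g. :class:`foldbridges.synthetic.TruncNormal`),
    the reference against which the empirical threshold inversion converges.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("posterior level must be in (0, 1)")
    prior_diff = 1.0 - prior_same

    def excess(s: float) -> float:
        num = prior_same * sibling_dist.sf(s)
        den = num + prior_diff * unrelated_dist.sf(s)
        return num / den - p if den > 0 else 1.0 - p

    lo = min(sibling_dist.low, unrelated_dist.low)
    hi = max(sibling_dist.high, unrelated_dist.high)
    return float(optimize.brentq(excess, lo + 1e-9, hi - 1e-9))


def write_threshold_table(results, path, levels=(0.5, 0.6, 0.7, 0.8, 0.9)) -> pd.DataFrame:
    """Export the effective-cutoff table (method x partition x level) as TSV."""
    table = pd.concat([r.threshold_table(levels) for r in results], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)
    return table
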