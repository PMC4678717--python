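"""Quantitative MDR statistic and cross-validated exhaustive pair search.

For a SNP pair, the 9 two-locus genotype cells are labelled *high* when
their training-set mean trait strictly exceeds the overall training mean,
*low* otherwise (*empty* when unpopulated).  High and low individuals are
pooled and compared with a pooled-variance two-sample t-statistic; the
statistic is evaluated out-of-fold under 10-fold cross-validation, and
pairs are ranked by their mean testing statistic.

Two evaluation paths exist: a scalar per-pair path
(:func:`assign_cells` / :func:`qmdr_t` / :func:`cross_validate_pair`) and
a vectorized batch path (:class:`PairSearch`) used by the exhaustive
search and the permutation machinery.  The batch path aggregates per-cell
trait sums / squared sums / counts with ``bincount`` so that scoring a
permuted trait costs no per-pair Python work.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING, GenotypeDataset
from .errors import DegenerateModelError

__all__ = [
    "FoldPlan",
    "CellAssignment",
    "QmdrModel",
    "assign_cells",
    "qmdr_t",
    "testing_t",
    "cross_validate_pair",
    "PairSearch",
    "exhaustive_search",
]

HIGH, LOW, EMPTY = "high", "low", "empty"


@dataclass(frozen=True)
class FoldPlan:
    """A seeded partition of samples into near-equal folds."""

    n_folds: int
    labels: np.ndarray  # per-sample fold index in [0, n_folds)
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.n_folds)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    @classmethod
    def make(cls, n_samples: int, n_folds: int = 10, seed: int = 0) -> "FoldPlan":
        """Uniform shuffle then round-robin assignment."""
        if n_samples < n_folds:
            raise ValueError(f"{n_samples} samples cannot fill {n_folds} folds")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_samples)
        labels = np.empty(n_samples, dtype=np.int64)
        labels[order] = np.arange(n_samples) % n_folds
        return cls(n_folds=n_folds, labels=labels, seed=seed)

    def train_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)

    def test_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)


@dataclass
class CellAssignment:
    """High/low/empty labels for the 9 two-locus genotype cells."""

    labels: np.ndarray  # 3x3 array of {"high","low","empty"}
    cell_means: np.ndarray  # 3x3 float, NaN for empty cells
    cell_counts: np.ndarray  # 3x3 int
    overall_mean: float

    def __post_init__(self) -> None:
        assert self.labels.shape == (3, 3)
        populated = self.cell_counts > 0
        assert ((self.labels == EMPTY) == ~populated).all()
        high = populated & (self.cell_means > self.overall_mean)
        assert ((self.labels == HIGH) == high).all()


def _pair_codes(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3*g1+g2 per sample; 9 where either call is missing."""
    codes = 3 * g1.astype(np.int64) + g2.astype(np.int64)
    codes[(g1 == MISSING) | (g2 == MISSING)] = 9
    return codes


def assign_cells(
    g1: np.ndarray,
    g2: np.ndarray,
    trait: np.ndarray,
    sample_subset: np.ndarray | None = None,
) -> CellAssignment:
    """Label each populated cell high/low against the subset's overall mean.

    Individuals missing either genotype are excluded; the overall mean is
    computed over the remaining members of ``sample_subset``.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    trait = np.asarray(trait, dtype=float)
    idx = np.arange(len(trait)) if sample_subset is None else np.asarray(sample_subset)
    codes = _pair_codes(g1[idx], g2[idx])
    ok = codes < 9
    if not ok.any():
        raise DegenerateModelError("all individuals missing a genotype for this pair")
    codes, y = codes[ok], trait[idx][ok]
    counts = np.bincount(codes, minlength=9)[:9]
    sums = np.bincount(codes, weights=y, minlength=9)[:9]
    overall = y.mean()
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    labels = np.full(9, LOW, dtype=object)
    labels[counts == 0] = EMPTY
    labels[(counts > 0) & (means > overall)] = HIGH
    return CellAssignment(
        labels=labels.reshape(3, 3),
        cell_means=means.reshape(3, 3),
        cell_counts=counts.reshape(3, 3),
        overall_mean=float(overall),
    )


def _pooled_t(
    n_h: float, s_h: float, ss_h: float, n_l: float, s_l: float, ss_l: float
) -> float:
    """Pooled-variance two-sample t from group sums; NaN when undefined
    (a group empty/singleton, or zero pooled variance)."""
    if n_h < 2 or n_l < 2:
        return math.nan
    var_h = ss_h - s_h * s_h / n_h
    var_l = ss_l - s_l * s_l / n_l
    sp2 = (var_h + var_l) / (n_h + n_l - 2)
    if sp2 <= 0:
        return math.nan
    return (s_h / n_h - s_l / n_l) / math.sqrt(sp2 * (1 / n_h + 1 / n_l))


def _group_t(
    codes: np.ndarray, y: np.ndarray, high_cells: np.ndarray, low_cells: np.ndarray
) -> float:
    hi = high_cells[codes]
    lo = low_cells[codes]
    yh, yl = y[hi], y[lo]
    return _pooled_t(
        len(yh), yh.sum(), (yh * yh).sum(), len(yl), yl.sum(), (yl * yl).sum()
    )


def qmdr_t(
    assignment: CellAssignment,
    g1: np.ndarray,
    g2: np.ndarray,
    trait: np.ndarray,
    sample_subset: np.ndarray | None = None,
) -> float:
    """Pooled two-sample t of high-cell vs low-cell individuals (high - low).

    Returns NaN (the undefined-statistic signal, ranked as -inf) when a
    pooled group is empty or singleton or the pooled variance is zero.
    """
    trait = np.asarray(trait, dtype=float)
    idx = np.arange(len(trait)) if sample_subset is None else np.asarray(sample_subset)
    codes = _pair_codes(np.asarray(g1)[idx], np.asarray(g2)[idx])
    ok = codes < 9
    flat = assignment.labels.ravel()
    high = np.append(flat == HIGH, False)
    low = np.append(flat == LOW, False)
    return _group_t(codes[ok], trait[idx][ok], high, low)


def testing_t(
    assignment: CellAssignment,
    g1: np.ndarray,
    g2: np.ndarray,
    trait: np.ndarray,
    sample_subset: np.ndarray,
    empty_cell_policy: str = "low",
) -> float:
    """Score held-out individuals with training-derived cell labels.

    ``empty_cell_policy`` controls individuals falling in cells that were
    empty during training: ``"low"`` pools them with the low group,
    ``"exclude"`` drops them.
    """
    trait = np.asarray(trait, dtype=float)
    idx = np.asarray(sample_subset)
    codes = _pair_codes(np.asarray(g1)[idx], np.asarray(g2)[idx])
    ok = codes < 9
    flat = assignment.labels.ravel()
    high = np.append(flat == HIGH, False)
    if empty_cell_policy == "low":
        low = np.append(flat != HIGH, False)
    elif empty_cell_policy == "exclude":
        low = np.append(flat == LOW, False)
    else:
        raise ValueError(f"unknown empty_cell_policy {empty_cell_policy!r}")
    return _group_t(codes[ok], trait[idx][ok], high, low)


def _nan_to_neginf(x: float) -> float:
    return -math.inf if math.isnan(x) else x


@dataclass
class QmdrModel:
    """A scored SNP pair: per-fold statistics and fold-mean summaries."""

    pair: tuple[str, str]
    train_t: np.ndarray  # per fold, NaN = undefined in that fold
    test_t: np.ndarray
    cvc: int | None = None  # folds in which this pair had the best training t

    def __post_init__(self) -> None:
        self.pair = (min(self.pair), max(self.pair))
        assert len(self.train_t) == len(self.test_t)

    @property
    def n_folds(self) -> int:
        return len(self.train_t)

    @property
    def mean_train_t(self) -> float:
        ok = ~np.isnan(self.train_t)
        return float(self.train_t[ok].mean()) if ok.any() else -math.inf

    @property
    def mean_test_t(self) -> float:
        ok = ~np.isnan(self.test_t)
        return float(self.test_t[ok].mean()) if ok.any() else -math.inf

    @property
    def has_undefined_folds(self) -> bool:
        return bool(np.isnan(self.train_t).any() or np.isnan(self.test_t).any())

    def sort_key(self) -> tuple:
        return (-self.mean_test_t, -self.mean_train_t, self.pair)


def cross_validate_pair(
    pair: tuple[str, str],
    dataset: GenotypeDataset,
    trait: np.ndarray,
    plan: FoldPlan,
    empty_cell_policy: str = "low",
) -> QmdrModel:
    """Per-fold training/testing statistics for one SNP pair (scalar path)."""
    if len(plan.labels) != dataset.n_samples:
        raise ValueError("fold plan does not cover the dataset")
    g1 = dataset.column(pair[0])
    g2 = dataset.column(pair[1])
    train = np.empty(plan.n_folds)
    test = np.empty(plan.n_folds)
    for f in range(plan.n_folds):
        tr, te = plan.train_idx(f), plan.test_idx(f)
        assignment = assign_cells(g1, g2, trait, tr)
        train[f] = qmdr_t(assignment, g1, g2, trait, tr)
        test[f] = testing_t(assignment, g1, g2, trait, te, empty_cell_policy)
    return QmdrModel(pair=tuple(pair), train_t=train, test_t=test)


class PairSearch:
    """Vectorized QMDR evaluation of many pairs under a fixed fold plan.

    Cell-level counts per fold depend only on the genotypes, so they are
    precomputed once; :meth:`score` then evaluates any trait vector (e.g.
    a permutation) with two weighted ``bincount`` calls per fold.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        pairs: list[tuple[str, str]],
        plan: FoldPlan,
        empty_cell_policy: str = "low",
    ) -> None:
        if len(plan.labels) != dataset.n_samples:
            raise ValueError("fold plan does not cover the dataset")
        if empty_cell_policy not in ("low", "exclude"):
            raise ValueError(f"unknown empty_cell_policy {empty_cell_policy!r}")
        self.pairs = [(min(p), max(p)) for p in pairs]
        self.plan = plan
        self.empty_cell_policy = empty_cell_policy
        n_pairs = len(self.pairs)
        col = {s: j for j, s in enumerate(dataset.snp_ids)}
        i1 = np.array([col[a] for a, _ in self.pairs])
        i2 = np.array([col[b] for _, b in self.pairs])
        G = dataset.calls
        codes = 3 * G[:, i1].astype(np.int64) + G[:, i2]
        codes[(G[:, i1] == MISSING) | (G[:, i2] == MISSING)] = 9
        codes = codes.T  # (n_pairs, n_samples)
        offsets = 10 * np.arange(n_pairs)[:, None]
        nbins = 10 * n_pairs
        self.n_pairs = n_pairs
        self._nbins = nbins
        # full-dataset flat codes; per-fold training aggregates are derived
        # as (full - test) so scoring a trait needs one full-size bincount
        # plus ten small test-fold bincounts
        self._flat_full = (codes + offsets).ravel()
        self._cnt_full = np.bincount(self._flat_full, minlength=nbins).reshape(
            n_pairs, 10
        )[:, :9]
        self._flat_test = []
        self._cnt_test = []
        self._test_idx = []
        for f in range(plan.n_folds):
            te = plan.test_idx(f)
            fte = (codes[:, te] + offsets).ravel()
            self._flat_test.append(fte)
            self._cnt_test.append(
                np.bincount(fte, minlength=nbins).reshape(n_pairs, 10)[:, :9]
            )
            self._test_idx.append(te)

    def _cell_sums(
        self, flat: np.ndarray, y_sub: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        w = np.tile(y_sub, self.n_pairs)
        s = np.bincount(flat, weights=w, minlength=self._nbins)
        ss = np.bincount(flat, weights=w * w, minlength=self._nbins)
        return (
            s.reshape(self.n_pairs, 10)[:, :9],
            ss.reshape(self.n_pairs, 10)[:, :9],
        )

    @staticmethod
    def _t_from_groups(n_h, s_h, ss_h, n_l, s_l, ss_l) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (ss_h - s_h**2 / np.maximum(n_h, 1)) + (
                ss_l - s_l**2 / np.maximum(n_l, 1)
            )
            sp2 = var / (n_h + n_l - 2)
            t = (s_h / n_h - s_l / n_l) / np.sqrt(sp2 * (1 / n_h + 1 / n_l))
        bad = (n_h < 2) | (n_l < 2) | ~(sp2 > 0)
        t = np.asarray(t, dtype=float)
        t[bad] = np.nan
        return t

    def score(self, trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_t, test_t), each of shape (n_pairs, n_folds)."""
        y = np.asarray(trait, dtype=float)
        train_t = np.empty((self.n_pairs, self.plan.n_folds))
        test_t = np.empty((self.n_pairs, self.plan.n_folds))
        s_full, ss_full = self._cell_sums(self._flat_full, y)
        for f in range(self.plan.n_folds):
            cnt_te_i = self._cnt_test[f]
            cnt = (self._cnt_full - cnt_te_i).astype(float)
            s_te, ss_te = self._cell_sums(self._flat_test[f], y[self._test_idx[f]])
            s = s_full - s_te
            ss = ss_full - ss_te
            tot_n = cnt.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                overall = s.sum(axis=1) / tot_n
                cell_mean = s / np.maximum(cnt, 1)
            high = (cnt > 0) & (cell_mean > overall[:, None])
            low_train = (cnt > 0) & ~high
            train_t[:, f] = self._t_from_groups(
                (cnt * high).sum(1),
                (s * high).sum(1),
                (ss * high).sum(1),
                (cnt * low_train).sum(1),
                (s * low_train).sum(1),
                (ss * low_train).sum(1),
            )
            cnt_te = cnt_te_i.astype(float)
            if self.empty_cell_policy == "low":
                low_test = ~high
            else:
                low_test = low_train
            test_t[:, f] = self._t_from_groups(
                (cnt_te * high).sum(1),
                (s_te * high).sum(1),
                (ss_te * high).sum(1),
                (cnt_te * low_test).sum(1),
                (s_te * low_test).sum(1),
                (ss_te * low_test).sum(1),
            )
        return train_t, test_t

    def mean_test_t(self, trait: np.ndarray) -> np.ndarray:
        """Fold-mean testing statistic per pair; -inf when every fold is
        undefined."""
        _, test_t = self.score(trait)
        ok = ~np.isnan(test_t)
        n_ok = ok.sum(axis=1)
        sums = np.where(ok, test_t, 0.0).sum(axis=1)
        return np.where(n_ok > 0, sums / np.maximum(n_ok, 1), -np.inf)


def _all_pairs(snp_ids: list[str]) -> list[tuple[str, str]]:
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(snp_ids), 2)]


def exhaustive_search(
    dataset: GenotypeDataset,
    trait: np.ndarray,
    plan: FoldPlan,
    candidate_snps: list[str] | None = None,
    candidate_pairs: list[tuple[str, str]] | None = None,
    top_k: int = 100,
    empty_cell_policy: str = "low",
) -> list[QmdrModel]:
    """Evaluate every candidate pair and return the ``top_k`` best models.

    Ranking: mean testing t (descending), ties by mean training t, then
    lexicographic pair id.  Cross-validation consistency (CVC) counts the
    folds in which each pair achieved the best training statistic.
    """
    if candidate_pairs is not None:
        pairs = sorted({(min(p), max(p)) for p in candidate_pairs})
    elif candidate_snps is not None:
        if len(candidate_snps) < 2:
            raise ValueError("need at least 2 candidate SNPs")
        pairs = _all_pairs(candidate_snps)
    else:
        pairs = _all_pairs(dataset.snp_ids)
    if not pairs:
        raise ValueError("no candidate pairs")

    search = PairSearch(dataset, pairs, plan, empty_cell_policy)
    train_t, test_t = search.score(trait)

    best_per_fold = np.argmax(np.nan_to_num(train_t, nan=-np.inf), axis=0)
    cvc = np.bincount(best_per_fold, minlength=len(pairs))

    models = [
        QmdrModel(pair=p, train_t=train_t[i], test_t=test_t[i], cvc=int(cvc[i]))
        for i, p in enumerate(search.pairs)
    ]
    models.sort(key=QmdrModel.sort_key)
    return models[:top_k]
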