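"""The error-consistency statistic and its pairwise summary.

Error consistency (EC) between two trained models is the Jaccard overlap of
their *error sets* — the held-out samples each model misclassified,
identified by sample id:

    EC(E_i, E_j) = |E_i ∩ E_j| / |E_i ∪ E_j|

When both error sets are empty the statistic is undefined (two perfect
classifiers leave no errors to be consistent on); this is represented by
NaN and propagated as a first-class value, never silently dropped.  Over a
collection of n error sets produced by repeated validation, only the
n(n−1)/2 upper-triangular pairs are computed (the diagonal is identically 1
and the matrix is symmetric), and the collection is summarised by the
average error consistency (AEC) and its standard deviation over the
*defined* pairs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

#: sentinel for an undefined error-consistency value (both error sets empty)
UNDEFINED = float("nan")

#: above this many error sets the full pairwise matrix is not materialised by
#: default; the AEC/SD summary is accumulated in row blocks instead
DEFAULT_PAIRWISE_CAP = 2000


def is_undefined(value: float) -> bool:
    """True when ``value`` is the undefined-EC sentinel."""
    return math.isnan(value)


@dataclass(frozen=True)
class ErrorSet:
    """The identities of held-out samples one trained model got wrong.

    Parameters
    ----------
    members
        Sample ids misclassified by the model.
    repetition
        Index of the validation repetition that produced the model.
    model_index
        Fold index of the model within the repetition (0 for the internal
        approach, where the K fold-wise error sets are united into one
        master set per repetition).
    support
        Sample ids on which predictions were made; ``members`` is always a
        subset of ``support``.
    """

    members: frozenset[int]
    repetition: int = 0
    model_index: int = 0
    support: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        support = frozenset(self.support) if self.support else self.members
        object.__setattr__(self, "support", support)
        if not self.support:
            raise InvalidInputError("an ErrorSet requires a non-empty support")
        if not self.members <= self.support:
            raise InvalidInputError("error-set members must lie within the support")

    @property
    def n_errors(self) -> int:
        return len(self.members)

    def accuracy(self) -> float:
        """Accuracy of the model on its support: 1 − |members| / |support|."""
        return 1.0 - len(self.members) / len(self.support)


def error_consistency(a: ErrorSet | frozenset[int] | set[int],
                      b: ErrorSet | frozenset[int] | set[int]) -> float:
    """Jaccard overlap of two error sets; NaN when both are empty."""
    sa = a.members if isinstance(a, ErrorSet) else frozenset(a)
    sb = b.members if isinstance(b, ErrorSet) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        return UNDEFINED
    return len(sa & sb) / union


@dataclass
class PairwiseEC:
    """Upper-triangular pairwise error-consistency values for n error sets.

    Entries are stored in lexicographic (i, j) order, i < j, as parallel
    arrays; undefined values are NaN.
    """

    n_sets: int
    i: np.ndarray  # int array, len n_sets*(n_sets-1)/2
    j: np.ndarray
    values: np.ndarray  # float array, NaN where undefined

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    @property
    def entries(self) -> Iterator[tuple[int, int, float]]:
        return zip(self.i.tolist(), self.j.tolist(), self.values.tolist())

    def defined_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    def to_frame(self):
        """Long-format DataFrame with columns (i, j, ec); NaN kept as NaN."""
        import pandas as pd

        return pd.DataFrame({"i": self.i, "j": self.j, "ec": self.values})

    def to_csv(self, path) -> None:
        """Write (i, j, ec) rows; undefined values become an empty field."""
        self.to_frame().to_csv(path, index=False, na_rep="")

    def to_json(self, path=None) -> str:
        entries = [
            [int(a), int(b), None if math.isnan(v) else v]
            for a, b, v in self.entries
        ]
        text = json.dumps({"n_sets": self.n_sets, "entries": entries})
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class ECSummary:
    """AEC/SD summary of the defined pairwise values.

    ``aec`` is NaN when no pair is defined; ``sd`` (sample standard
    deviation, n−1 denominator) is NaN when fewer than two pairs are
    defined.
    """

    aec: float
    sd: float
    n_pairs_defined: int
    n_pairs_undefined: int

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_defined + self.n_pairs_undefined

    @property
    def defined(self) -> bool:
        return self.n_pairs_defined > 0


def _membership_matrix(sets: Sequence[ErrorSet | frozenset[int] | set[int]]):
    """Boolean (n_sets × n_ids) membership matrix over the union of ids."""
    members = [s.members if isinstance(s, ErrorSet) else frozenset(s) for s in sets]
    universe = sorted(set().union(*members)) if members else []
    col = {sid: c for c, sid in enumerate(universe)}
    mat = np.zeros((len(members), len(universe)), dtype=bool)
    for r, ms in enumerate(members):
        for sid in ms:
            mat[r, col[sid]] = True
    return mat


def pairwise_ec(sets: Sequence[ErrorSet | frozenset[int] | set[int]]) -> PairwiseEC:
    """All n(n−1)/2 pairwise error-consistency values, i < j lexicographic."""
    n = len(sets)
    if n < 2:
        raise InvalidInputError(f"pairwise EC needs at least 2 error sets, got {n}")
    mat = _membership_matrix(sets)
    sizes = mat.sum(axis=1)
    inter = (mat.astype(np.int64) @ mat.T.astype(np.int64)) if mat.shape[1] else np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    inter_u = inter[iu, ju].astype(float)
    union_u = (sizes[iu] + sizes[ju] - inter_u).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union_u > 0, inter_u / np.maximum(union_u, 1), UNDEFINED)
    values[union_u == 0] = UNDEFINED
    return PairwiseEC(n_sets=n, i=iu, j=ju, values=values)


def summarize_ec(pec: PairwiseEC) -> ECSummary:
    """AEC (mean) and SD over the defined pairwise values.

    Undefined pairs are counted in ``n_pairs_undefined`` and excluded from
    both moments; a warning is logged whenever any pair is undefined.
    """
    defined = pec.defined_values()
    n_def = len(defined)
    n_undef = pec.n_pairs - n_def
    if n_undef > 0:
        logger.warning(
            "%d of %d pairwise error-consistency values are undefined "
            "(both error sets empty) and excluded from the AEC/SD summary",
            n_undef, pec.n_pairs,
        )
    aec = float(np.mean(defined)) if n_def else UNDEFINED
    sd = float(np.std(defined, ddof=1)) if n_def >= 2 else UNDEFINED
    return ECSummary(aec=aec, sd=sd, n_pairs_defined=n_def, n_pairs_undefined=n_undef)


def summarize_error_sets(
    sets: Sequence[ErrorSet | frozenset[int] | set[int]],
    pairwise_cap: int = DEFAULT_PAIRWISE_CAP,
    block: int = 256,
) -> ECSummary:
    """AEC/SD summary of a collection of error sets.

    For up to ``pairwise_cap`` sets the full :class:`PairwiseEC` is
    materialised; beyond that the n(n−1)/2 values are accumulated in row
    blocks (running count/sum/sum-of-squares) so memory stays linear in n.
    Both routes produce identical summaries.
    """
    n = len(sets)
    if n < 2:
        raise InvalidInputError(f"EC summary needs at least 2 error sets, got {n}")
    if n <= pairwise_cap:
        return summarize_ec(pairwise_ec(sets))

    mat = _membership_matrix(sets)
    sizes = mat.sum(axis=1).astype(np.int64)
    count = 0
    total = 0.0
    total_sq = 0.0
    n_undef = 0
    mi = mat.astype(np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        inter = mi[start:stop] @ mi.T
        # keep only j > i for each row of the block
        for local, i_row in enumerate(range(start, stop)):
            row_inter = inter[local, i_row + 1:]
            row_union = sizes[i_row] + sizes[i_row + 1:] - row_inter
            undef = row_union == 0
            n_undef += int(undef.sum())
            vals = row_inter[~undef] / row_union[~undef]
            count += vals.size
            total += float(vals.sum())
            total_sq += float((vals * vals).sum())
    if n_undef > 0:
        logger.warning(
            "%d of %d pairwise error-consistency values are undefined "
            "(both error sets empty) and excluded from the AEC/SD summary",
            n_undef, count + n_undef,
        )
    if count == 0:
        return ECSummary(UNDEFINED, UNDEFINED, 0, n_undef)
    aec = total / count
    sd = UNDEFINED
    if count >= 2:
        var = max(total_sq - count * aec * aec, 0.0) / (count - 1)
        sd = math.sqrt(var)
    return ECSummary(aec=aec, sd=sd, n_pairs_defined=count, n_pairs_undefined=n_undef)
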