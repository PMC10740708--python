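"""Output-importance ranking by minimum-redundancy maximum-relevance.

Relevance of an output is its mutual information (MI) with the binary
hypothesis label; redundancy is its mean MI with already-selected
outputs.  The mutual information quotient MIQ = relevance / redundancy
ranks outputs after the first (which is picked by maximal relevance).
Importance scores follow the recursive rule: the top-ranked output's
score is its relevance, and each later score is the previous score
multiplied by the ratio of the current MIQ to the previous MIQ.

MI is estimated with the plug-in (empirical joint histogram) estimator
on quantile bins, which makes every score invariant under strictly
monotone transforms of the outputs — in particular the linear/log scale
choice does not matter here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CellTable

logger = logging.getLogger("celldecide")

#: quantile bins per continuous output for the plug-in MI estimator
DEFAULT_BINS = 16
#: a variable with at most this many distinct values is treated as discrete
_DISCRETE_MAX = 32


def discretize(values: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Map a variable to integer codes.

    Already-discrete variables (≤ 32 distinct values, e.g. hypothesis
    labels) are factorised as-is; continuous ones are cut at empirical
    quantiles into at most ``bins`` occupied bins.
    """
    values = np.asarray(values)
    uniq = pd.unique(values)
    if len(uniq) <= min(bins, _DISCRETE_MAX):
        codes, _ = pd.factorize(values)
        return codes
    qs = np.quantile(values.astype(float), np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), values, side="right")


def mutual_information(
    a: np.ndarray, b: np.ndarray, base: float = 2.0
) -> float:
    """Plug-in mutual information between two discretised variables.

    I(A; B) = Σ p(a,b) log[p(a,b) / (p(a)p(b))] over the empirical joint
    distribution; nonnegative and symmetric.  ``base=2`` gives bits
    (default), ``base=np.e`` nats.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ca, _ = pd.factorize(a)
    cb, _ = pd.factorize(b)
    joint = np.zeros((ca.max() + 1, cb.max() + 1))
    np.add.at(joint, (ca, cb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0) / np.log(base)


@dataclass
class ImportanceReport:
    """MRMR ranking of the outputs with per-output diagnostics.

    ``ranking`` is best-first.  For each output: ``relevance`` (MI with
    the hypothesis label), ``redundancy`` (mean MI with the outputs
    ranked above it; for the top output, the mean MI with all the
    others, used as the floor that keeps its MIQ finite), ``miq`` and
    the recursive importance ``score``.  ``unit`` is "bit" or "nat".
    """

    ranking: list[str]
    relevance: dict[str, float]
    redundancy: dict[str, float]
    miq: dict[str, float]
    score: dict[str, float]
    unit: str = "bit"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "output": self.ranking,
                "relevance": [self.relevance[o] for o in self.ranking],
                "redundancy": [self.redundancy[o] for o in self.ranking],
                "miq": [self.miq[o] for o in self.ranking],
                "score": [self.score[o] for o in self.ranking],
            }
        )


def mrmr_importance(
    table: CellTable,
    hypothesis_labels: np.ndarray,
    outputs: list[str] | None = None,
    bins: int = DEFAULT_BINS,
    unit: str = "bit",
) -> ImportanceReport:
    """Rank outputs by MRMR/MIQ and compute recursive importance scores.

    ``hypothesis_labels`` assigns each cell of ``table`` its hypothesis
    (0/1 or any two labels).  Outputs are quantile-discretised before
    MI estimation.  Rank 1 maximises relevance; later ranks maximise
    MIQ against the already-selected set; ties break by input order
    (logged).  score(1) = relevance(1);
    score(k) = score(k-1) · MIQ(k) / MIQ(k-1).
    """
    if outputs is None:
        outputs = list(table.outputs)
    if len(outputs) < 2:
        raise ValueError("mrmr_importance requires at least 2 outputs")
    labels = np.asarray(hypothesis_labels).ravel()
    if len(labels) != len(table):
        raise ValueError("one hypothesis label per cell is required")
    if len(pd.unique(labels)) < 2:
        raise ValueError("both hypothesis labels must be present")
    base = {"bit": 2.0, "nat": np.e}[unit]

    codes = {
        o: discretize(table.data[o].to_numpy(dtype=float), bins) for o in outputs
    }
    relevance = {o: mutual_information(codes[o], labels, base=base) for o in outputs}
    pair_mi = {
        (a, b): mutual_information(codes[a], codes[b], base=base)
        for i, a in enumerate(outputs)
        for b in outputs[i + 1:]
    }

    def mi_between(a: str, b: str) -> float:
        return pair_mi.get((a, b), pair_mi.get((b, a), 0.0))

    rel_arr = np.array([relevance[o] for o in outputs])
    if np.sum(rel_arr == rel_arr.max()) > 1:
        logger.warning("mrmr_importance: relevance tie broken by input order")
    first = outputs[int(np.argmax(rel_arr))]

    ranking = [first]
    remaining = [o for o in outputs if o != first]
    redundancy: dict[str, float] = {}
    miq: dict[str, float] = {}
    # the top output has no selected set; floor its redundancy at its mean
    # MI with the remaining outputs so its MIQ stays finite
    eps_hat = float(np.mean([mi_between(first, o) for o in remaining]))
    redundancy[first] = eps_hat
    miq[first] = relevance[first] / eps_hat if eps_hat > 0 else np.inf

    while remaining:
        cand_red = {
            o: float(np.mean([mi_between(o, s) for s in ranking])) for o in remaining
        }
        cand_miq = {
            o: (relevance[o] / cand_red[o]) if cand_red[o] > 0 else np.inf
            for o in remaining
        }
        vals = np.array([cand_miq[o] for o in remaining])
        if np.sum(vals == vals.max()) > 1:
            logger.warning("mrmr_importance: MIQ tie broken by input order")
        chosen = remaining[int(np.argmax(vals))]
        redundancy[chosen] = cand_red[chosen]
        miq[chosen] = cand_miq[chosen]
        ranking.append(chosen)
        remaining.remove(chosen)

    score: dict[str, float] = {ranking[0]: relevance[ranking[0]]}
    for prev, cur in zip(ranking[:-1], ranking[1:]):
        if np.isinf(miq[prev]):
            score[cur] = 0.0
        else:
            score[cur] = score[prev] * miq[cur] / miq[prev]

    return ImportanceReport(
        ranking=ranking,
        relevance=relevance,
        redundancy=redundancy,
        miq=miq,
        score=score,
        unit=unit,
    )
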