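"""Term enrichment and regulator-activation statistics.

Two statistics are provided:

* cumulative hypergeometric over-representation: for a query of s genes
  drawn from a universe of r genes, of which k are annotated to a term and x
  overlap the query, p = P(X >= x) under X ~ Hypergeom(r, k, s) — the upper
  tail 1 - sum_{i<x} C(k,i) C(r-k, s-i) / C(r,s); BH correction across terms.

* activation z-score: over the genes shared between a regulator's known
  targets and an observed expression change, N+ counts direction-concordant
  genes (product of expected and observed direction > 0), N- discordant, and
  z = (N+ - N-) / sqrt(N+ + N-); z > 0 predicts activation, z < 0 inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust


@dataclass
class EnrichmentResult:
    term: str
    k: int  # genes annotated to the term (within the universe)
    r: int  # universe size
    s: int  # query size
    x: int  # overlap
    p: float
    q: float = float("nan")


def hypergeometric_p(x: int, r: int, k: int, s: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeom(population r, successes k, draws s)."""
    if x <= 0:
        return 1.0
    return float(hypergeom.sf(x - 1, r, k, s))


def hypergeometric_enrichment(
    query: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Over-representation of each term set in the query, BH-corrected.

    Every term set is first intersected with the universe; the query must be
    a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    r, s = len(uni), len(q)
    results = []
    for term, genes in term_sets.items():
        annotated = set(genes) & uni
        k = len(annotated)
        x = len(annotated & q)
        results.append(EnrichmentResult(term=term, k=k, r=r, s=s, x=x, p=hypergeometric_p(x, r, k, s)))
    qs = bh_adjust(np.array([res.p for res in results])) if results else []
    for res, qv in zip(results, qs):
        res.q = float(qv)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": e.term, "k": e.k, "r": e.r, "s": e.s, "x": e.x, "p": e.p, "q": e.q}
            for e in results
        ]
    )


@dataclass
class ActivationScore:
    regulator: str
    n_plus: int
    n_minus: int
    z: float | None  # None when the overlap is empty (undefined)

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def state(self) -> str:
        if self.z is None:
            return "undefined"
        if self.z > 0:
            return "activating"
        if self.z < 0:
            return "inhibiting"
        return "neutral"


def activation_zscore(
    regulator: str,
    expected_direction: Mapping[str, int],
    observed_direction: Mapping[str, int],
) -> ActivationScore:
    """z = (N+ - N-) / sqrt(N+ + N-) over the overlap of the two maps.

    Directions must be nonzero (+1/-1 signs); a gene contributes to N+ when
    expected * observed > 0 and to N- otherwise.  An empty overlap leaves z
    undefined (flagged None).
    """
    overlap = set(expected_direction) & set(observed_direction)
    n_plus = n_minus = 0
    for g in overlap:
        e, o = expected_direction[g], observed_direction[g]
        if e == 0 or o == 0:
            raise ValueError(f"gene {g!r} has a zero direction")
        if e * o > 0:
            n_plus += 1
        else:
            n_minus += 1
    if n_plus + n_minus == 0:
        return ActivationScore(regulator, 0, 0, None)
    z = (n_plus - n_minus) / np.sqrt(n_plus + n_minus)
    return ActivationScore(regulator, n_plus, n_minus, float(z))
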