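"""Recovery evaluation helpers: matching discovered programs to truth."""

from __future__ import annotations

from .datamodel import GeneSetCollection

__all__ = ["jaccard", "best_match_jaccard"]


def jaccard(a: set[str] | list[str], b: set[str] | list[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def best_match_jaccard(
    truth: GeneSetCollection, discovered: GeneSetCollection
) -> dict[str, tuple[str | None, float]]:
    """For each truth set, the best-matching discovered set by Jaccard."""
    out: dict[str, tuple[str | None, float]] = {}
    for name, genes in truth:
        best_name, best_j = None, 0.0
        for dname, dgenes in discovered:
            j = jaccard(genes, dgenes)
            if j > best_j:
                best_name, best_j = dname, j
        out[name] = (best_name, best_j)
    return out
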