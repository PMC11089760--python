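"""Tripartite lncRNA-miRNA-disease graph: container, edge-list I/O and
neighborhood primitives.

The graph has three disjoint vertex classes -- lncRNAs ``L``, miRNAs ``M``
and diseases ``D`` -- and two edge sets: lncRNA-miRNA interactions (LMI,
``I``) and miRNA-disease associations (MDA, ``A``).  All prediction methods
in this package consume this container.  Identifiers are opaque,
case-sensitive database symbols; no normalisation is attempted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

__all__ = ["TripartiteGraph", "read_edge_list", "build_tripartite"]


def _check_id(value: str, role: str) -> str:
    if not isinstance(value, str) or not value:
        raise ValueError(f"{role} identifier must be a non-empty string, got {value!r}")
    if "\t" in value or "\n" in value:
        raise ValueError(f"{role} identifier {value!r} contains a tab or newline")
    return value


class TripartiteGraph:
    """Immutable tripartite graph over lncRNAs, miRNAs and diseases.

    Parameters
    ----------
    lmi : iterable of (lncRNA, miRNA) pairs
        Experimentally validated lncRNA-miRNA interactions.
    mda : iterable of (miRNA, disease) pairs
        Known miRNA-disease associations.
    lncrnas, mirnas, diseases : iterable of str, optional
        Extra (possibly isolated, degree-0) vertices to include beyond the
        ones implied by the edge lists, so that every lncRNA x disease pair
        of the study universe can be ranked.
    """

    def __init__(
        self,
        lmi: Iterable[Pair],
        mda: Iterable[Pair],
        lncrnas: Iterable[str] = (),
        mirnas: Iterable[str] = (),
        diseases: Iterable[str] = (),
    ) -> None:
        self.lmi: frozenset[Pair] = frozenset((str(a), str(b)) for a, b in lmi)
        self.mda: frozenset[Pair] = frozenset((str(a), str(b)) for a, b in mda)

        L = {l for l, _ in self.lmi} | set(lncrnas)
        M = {m for _, m in self.lmi} | {m for m, _ in self.mda} | set(mirnas)
        D = {d for _, d in self.mda} | set(diseases)
        for l in L:
            _check_id(l, "lncRNA")
        for m in M:
            _check_id(m, "miRNA")
        for d in D:
            _check_id(d, "disease")
        for a, b, na, nb in (
            (L, M, "lncRNA", "miRNA"),
            (M, D, "miRNA", "disease"),
            (L, D, "lncRNA", "disease"),
        ):
            clash = a & b
            if clash:
                raise ValueError(
                    f"identifier(s) used both as {na} and {nb}: {sorted(clash)[:5]}"
                )
        self.lncrnas: frozenset[str] = frozenset(L)
        self.mirnas: frozenset[str] = frozenset(M)
        self.diseases: frozenset[str] = frozenset(D)

        mol: dict[str, set[str]] = {l: set() for l in L}
        for l, m in self.lmi:
            mol[l].add(m)
        mod: dict[str, set[str]] = {d: set() for d in D}
        for m, d in self.mda:
            mod[d].add(m)
        self._mir_of_lnc = {l: frozenset(s) for l, s in mol.items()}
        self._mir_of_dis = {d: frozenset(s) for d, s in mod.items()}
        self._neighbors: dict[str, frozenset[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_lmi(self) -> int:
        return len(self.lmi)

    @property
    def n_mda(self) -> int:
        return len(self.mda)

    def mirna_profile_lncrna(self, l: str) -> frozenset[str]:
        """miRNAs interacting with lncRNA ``l`` (the set M_l)."""
        try:
            return self._mir_of_lnc[l]
        except KeyError:
            raise KeyError(f"unknown lncRNA {l!r}") from None

    def mirna_profile_disease(self, d: str) -> frozenset[str]:
        """miRNAs associated with disease ``d`` (the set M_d)."""
        try:
            return self._mir_of_dis[d]
        except KeyError:
            raise KeyError(f"unknown disease {d!r}") from None

    def neighbors(self, l: str) -> frozenset[str]:
        """Other lncRNAs sharing at least one interacting miRNA with ``l``.

        ``l`` itself is never a member (a vertex is not its own neighbor;
        including it would double-count the direct term of the prediction
        score).
        """
        cached = self._neighbors.get(l)
        if cached is not None:
            return cached
        prof = self.mirna_profile_lncrna(l)
        nbrs = frozenset(
            other
            for other, oprof in self._mir_of_lnc.items()
            if other != l and prof & oprof
        )
        self._neighbors[l] = nbrs
        return nbrs

    # -- dunder helpers ----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripartiteGraph):
            return NotImplemented
        return (
            self.lncrnas == other.lncrnas
            and self.mirnas == other.mirnas
            and self.diseases == other.diseases
            and self.lmi == other.lmi
            and self.mda == other.mda
        )

    def __hash__(self) -> int:
        return hash((self.lncrnas, self.mirnas, self.diseases, self.lmi, self.mda))

    def __repr__(self) -> str:
        return (
            f"TripartiteGraph(|L|={len(self.lncrnas)}, |M|={len(self.mirnas)}, "
            f"|D|={len(self.diseases)}, |I|={self.n_lmi}, |A|={self.n_mda})"
        )


def read_edge_list(path, kind: str = "lmi", sep: str = "\t") -> set[Pair]:
    """Read a two-column edge list into a de-duplicated set of ordered pairs.

    Blank lines and lines starting with ``#`` are skipped; surrounding
    whitespace is trimmed from each field.  ``sep`` defaults to tab; pass
    ``","`` for comma-separated files.

    Raises
    ------
    ValueError
        If a non-comment line has fewer than two usable fields (the error
        names the 1-based line number).
    """
    pairs: set[Pair] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: malformed {kind} line {lineno}: need >=2 "
                    f"{'tab' if sep == chr(9) else repr(sep)}-separated fields, got {line!r}"
                )
            pairs.add((fields[0], fields[1]))
    if not pairs:
        logger.warning("%s: empty %s edge list", path, kind)
    return pairs


def write_edge_list(pairs: Iterable[Pair], path) -> None:
    """Write pairs as a sorted tab-separated two-column file."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def build_tripartite(
    lmi: Iterable[Pair],
    mda: Iterable[Pair],
    lncrnas: Iterable[str] = (),
    mirnas: Iterable[str] = (),
    diseases: Iterable[str] = (),
) -> TripartiteGraph:
    """Assemble a :class:`TripartiteGraph` from LMI and MDA pair sets.

    lncRNAs are those appearing in ``lmi``, miRNAs those in ``lmi`` or
    ``mda``, diseases those in ``mda``; the optional vertex lists inject
    isolated entities into the ranked universe.
    """
    return TripartiteGraph(lmi, mda, lncrnas=lncrnas, mirnas=mirnas, diseases=diseases)
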