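"""Rule-based curation of LTR retrotransposon libraries.

Implements the conventional-bioinformatics arm of the curator: scan each
element for lineage-diagnostic domain motifs and terminal-inverted-repeat
(TIR) pairs, then assign a curation label by a deterministic cascade:

1. domains from two superfamilies present        -> label 1
2. else domains from two lineages present        -> label 2
3. else a TIR pair present (Class II insertion)  -> label 4
4. else total length outside the lineage's
   literature range ± tolerance (20% default)    -> label 3
5. else intact                                   -> label 0

Structural contamination (1, 2, 4) outranks the length symptom it causes,
so the cascade is checked in the order 1 -> 2 -> 4 -> 3.  Elements with no
detected domain at all are reported as unclassifiable (``None``), never
silently as intact.

The domain scan here is exact motif matching against a configured lineage
library; it sits behind this module's interface so that a homology or
profile-search backend could be substituted without touching the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .sim import LineageSpec, SequenceRecord, Superfamily, reverse_complement

__all__ = [
    "DomainHit",
    "ElementAnnotation",
    "CurationLabel",
    "annotate_domains",
    "assign_label",
    "binarize",
    "length_table",
    "label_records",
    "write_label_table",
]


@dataclass(frozen=True)
class DomainHit:
    """One motif occurrence: 0-based half-open coordinates."""

    domain: str
    lineage: str
    superfamily: Superfamily
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")


@dataclass
class ElementAnnotation:
    seq_id: str
    length: int
    hits: list[DomainHit] = field(default_factory=list)
    #: (start, end) intervals of detected TIR pairs (Class II insertions)
    class2_hits: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits.sort(key=lambda h: (h.start, h.end))
        for h in self.hits:
            if h.end > self.length:
                raise ValueError(f"hit {h} exceeds sequence length {self.length}")
        for s, e in self.class2_hits:
            if not 0 <= s < e <= self.length:
                raise ValueError("class2 interval out of bounds")


@dataclass(frozen=True)
class CurationLabel:
    """Curation verdict: 0 intact, 1-4 the four contamination classes."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3, 4):
            raise ValueError("label must be in 0..4")

    @property
    def binary(self) -> int:
        """0 = keep (intact), 1 = remove (any contamination class)."""
        return 0 if self.value == 0 else 1


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def annotate_domains(seq: SequenceRecord, library: Sequence[LineageSpec],
                     class2_motifs: Sequence[str] = (), *,
                     max_tir_span: int = 2000,
                     both_strands: bool = False) -> ElementAnnotation:
    """Report every occurrence of every library domain motif plus every TIR
    pair (motif ... reverse complement within ``max_tir_span``).

    The forward strand is scanned by default; ``both_strands`` additionally
    scans for reverse-complemented domain motifs (strand ``-``).
    """
    s = seq.seq.upper()
    if not s:
        raise ValueError("empty sequence")
    hits: list[DomainHit] = []
    for spec in library:
        for domain, motif in spec.domain_motifs:
            for pos in _find_all(s, motif):
                hits.append(DomainHit(domain, spec.name, spec.superfamily,
                                      pos, pos + len(motif)))
            if both_strands:
                rc = reverse_complement(motif)
                for pos in _find_all(s, rc):
                    hits.append(DomainHit(domain, spec.name, spec.superfamily,
                                          pos, pos + len(motif), strand="-"))
    class2: list[tuple[int, int]] = []
    for motif in class2_motifs:
        lefts = _find_all(s, motif)
        rights = _find_all(s, reverse_complement(motif))
        used: set[int] = set()
        for lpos in lefts:
            for rpos in rights:
                if rpos in used or rpos <= lpos:
                    continue
                end = rpos + len(motif)
                if end - lpos <= max_tir_span:
                    class2.append((lpos, end))
                    used.add(rpos)
                    break
    return ElementAnnotation(seq.id, len(s), hits, sorted(class2))


def length_table(library: Sequence[LineageSpec]) -> dict[str, tuple[int, int]]:
    """Lineage name -> literature total-length interval."""
    return {spec.name: spec.total_len_range for spec in library}


def assign_label(ann: ElementAnnotation,
                 library: Sequence[LineageSpec] | Mapping[str, tuple[int, int]],
                 tolerance: float = 0.20, *,
                 symmetric: bool = True) -> Optional[CurationLabel]:
    """Apply the curation cascade (1 -> 2 -> 4 -> 3 -> 0) to an annotation.

    ``library`` supplies the per-lineage length intervals for the length
    filter (a lineage-spec list or a precomputed ``length_table``).  The
    length check is symmetric (±tolerance) by default; ``symmetric=False``
    fires only on length increase.  Returns ``None`` for elements with zero
    domain hits (unclassifiable).
    """
    if not ann.hits:
        return None
    if len({h.superfamily for h in ann.hits}) >= 2:
        return CurationLabel(1)
    lineages = {h.lineage for h in ann.hits}
    if len(lineages) >= 2:
        return CurationLabel(2)
    if ann.class2_hits:
        return CurationLabel(4)
    table = length_table(library) if not isinstance(library, Mapping) else library
    lo, hi = table[next(iter(lineages))]
    lower = lo * (1 - tolerance) if symmetric else 0.0
    if not lower <= ann.length <= hi * (1 + tolerance):
        return CurationLabel(3)
    return CurationLabel(0)


def binarize(label: CurationLabel | int) -> int:
    """Two-label collapse: intact (0) vs any contamination class (1)."""
    value = label.value if isinstance(label, CurationLabel) else int(label)
    return CurationLabel(value).binary


def label_records(records: Sequence[SequenceRecord],
                  library: Sequence[LineageSpec],
                  class2_motifs: Sequence[str] = (),
                  tolerance: float = 0.20, *,
                  symmetric: bool = True) -> list[Optional[CurationLabel]]:
    """Annotate and label a batch of records (``None`` = unclassifiable)."""
    table = length_table(library)
    return [assign_label(annotate_domains(r, library, class2_motifs), table,
                         tolerance, symmetric=symmetric)
            for r in records]


def write_label_table(records: Sequence[SequenceRecord],
                      labels: Sequence[Optional[CurationLabel]],
                      path: str | Path) -> None:
    """TSV: seq_id, label (or ``unclassifiable``), binary."""
    with open(path, "w") as fh:
        fh.write("seq_id\tlabel\tbinary\n")
        for rec, lab in zip(records, labels):
            if lab is None:
                fh.write(f"{rec.id}\tunclassifiable\t\n")
            else:
                fh.write(f"{rec.id}\t{lab.value}\t{lab.binary}\n")
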