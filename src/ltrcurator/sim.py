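"""Synthetic LTR retrotransposon datasets with recoverable ground truth.

Generates labeled libraries of nucleotide sequences that emulate the
structure of plant LTR retrotransposons (LTR-RTs): two identical long
terminal repeats flanking an internal region that carries the coding
domains (GAG, AP, INT, RT, RH) in a superfamily-specific order — Copia
places INT before RT, Gypsy places RT-RH before INT.  Each lineage is
identified by a private motif per domain, so the rule-based curation
filters can recover every label exactly.

Five classes are produced:

====  =========================================================
0     intact element (keep)
1     nested LTR-RT insertion from the other superfamily
2     nested LTR-RT insertion from another lineage, same superfamily
3     length anomaly: element longer than the lineage's literature
      range by more than the curation tolerance (20% by default)
4     Class II (TIR transposon) insertion, flanked by terminal
      inverted repeats
====  =========================================================

Background sequence is i.i.d. under a per-lineage base composition —
real TE lineages carry distinct global k-mer signatures, which is what
makes k-mer classification of transposable elements work at all — and is
rejection-sampled so that no library motif (nor the TIR pair) ever
occurs by chance, which makes label recovery exact rather than merely
overwhelmingly probable.  Nested elements therefore mix two lineage
signatures, Class II insertions add an AT-rich segment, while length
anomalies keep the host composition (only their length separates them
from intact elements, which makes them the hard class).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Superfamily",
    "LineageSpec",
    "SimConfig",
    "SequenceRecord",
    "LabeledDataset",
    "DOMAIN_ORDER",
    "PAPER_CLASS_COUNTS",
    "reverse_complement",
    "imbalanced_counts",
    "make_lineage_library",
    "simulate_intact",
    "simulate_nested",
    "simulate_length_anomaly",
    "simulate_class2_insertion",
    "generate_dataset",
    "write_fasta",
    "write_labels",
    "read_fasta",
    "read_labels",
    "library_to_yaml",
    "library_from_yaml",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Class sizes of the reference training corpus (classes 0..4); used to
#: derive the default imbalance when a dataset of a given total size is
#: requested.
PAPER_CLASS_COUNTS = (56442, 33874, 4734, 8568, 2039)

#: Default TIR motif marking Class II (DNA transposon) insertions; the
#: insertion is this motif, a random spacer, then its reverse complement.
DEFAULT_TIR_MOTIF = "CACTACAAGAAATTGTGACCGTTG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Superfamily(str, Enum):
    GYPSY = "GYPSY"
    COPIA = "COPIA"


#: Internal protein-domain order by superfamily (Copia: INT before RT;
#: Gypsy: RT-RH before INT).
DOMAIN_ORDER: dict[Superfamily, tuple[str, ...]] = {
    Superfamily.COPIA: ("GAG", "AP", "INT", "RT", "RH"),
    Superfamily.GYPSY: ("GAG", "AP", "RT", "RH", "INT"),
}


@dataclass(frozen=True)
class LineageSpec:
    """One synthetic lineage: length ranges plus a private motif per domain."""

    name: str
    superfamily: Superfamily
    ltr_len_range: tuple[int, int]
    total_len_range: tuple[int, int]
    #: ordered (domain_name, motif) pairs following the superfamily order
    domain_motifs: tuple[tuple[str, str], ...]
    #: background base probabilities (A, C, G, T); the lineage's global
    #: composition signature.  None falls back to a symmetric composition.
    base_freqs: tuple[float, float, float, float] | None = None
    #: base probabilities of the coding domain bodies (GAG/AP/INT/RT/RH are
    #: kilobase-scale coding regions in real elements, with a composition
    #: distinct from intergenic background).  None falls back to base_freqs.
    coding_freqs: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        for freqs in (self.base_freqs, self.coding_freqs):
            if freqs is not None:
                if len(freqs) != 4 or abs(sum(freqs) - 1) > 1e-6:
                    raise ValueError("base probabilities must sum to 1")
        lo, hi = self.ltr_len_range
        tlo, thi = self.total_len_range
        if not (0 < lo <= hi and 0 < tlo <= thi):
            raise ValueError("length ranges must be positive and ordered")
        if tlo < 2 * lo:
            raise ValueError("total length min must be >= 2x LTR length min")
        order = DOMAIN_ORDER[self.superfamily]
        if tuple(d for d, _ in self.domain_motifs) != order:
            raise ValueError(f"domain order for {self.superfamily} must be {order}")

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(m for _, m in self.domain_motifs)


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence over {A,C,G,T,N} with an identifier."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``n_per_class`` gives the number of records for classes 0..4.  The
    curation tolerance is the same ±20% band the length filter uses, so a
    Class II insertion never also trips the length filter.
    """

    n_per_class: tuple[int, int, int, int, int]
    seed: int = 0
    #: fallback GC for lineage specs without their own base composition
    gc_content: float = 0.42
    tir_motif: str = DEFAULT_TIR_MOTIF
    #: interior composition of Class II inserts (AT-rich, MITE-like)
    class2_base_freqs: tuple[float, float, float, float] = (0.41, 0.09, 0.09, 0.41)
    #: interior length range of Class II inserts (bp), clamped so the
    #: insertion never trips the ±tolerance length filter
    class2_insert_len_range: tuple[int, int] = (300, 1000)
    length_tolerance: float = 0.20
    #: class-3 lengths are drawn as (factor x range max) with factor in this
    #: interval; the low end sits just above 1 + tolerance, so the shortest
    #: anomalies genuinely overlap intact elements in composition space
    #: (length itself is invisible to frequency features), keeping class 3
    #: the hard class, while the long tail emulates run-on predictions and
    #: unresolved tandem nests that can approach twice the true length.
    anomaly_factor_range: tuple[float, float] = (1.25, 1.80)

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 5 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be five non-negative counts")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0.0 < self.length_tolerance < 1.0:
            raise ValueError("length_tolerance must be in (0, 1)")
        if self.anomaly_factor_range[0] <= 1.0 + self.length_tolerance:
            raise ValueError("anomaly factors must exceed 1 + tolerance")


@dataclass
class LabeledDataset:
    """Aligned records, integer labels 0..4 and per-record provenance notes."""

    records: list[SequenceRecord]
    labels: list[int]
    provenance: list[str]

    def __post_init__(self) -> None:
        if not (len(self.records) == len(self.labels) == len(self.provenance)):
            raise ValueError("records, labels and provenance must align")
        if any(l not in (0, 1, 2, 3, 4) for l in self.labels):
            raise ValueError("labels must be in 0..4")

    def __len__(self) -> int:
        return len(self.records)


def imbalanced_counts(total: int) -> tuple[int, int, int, int, int]:
    """Class counts for a dataset of ``total`` records at the reference
    imbalance (largest-remainder apportionment of 56442:33874:4734:8568:2039).
    """
    if total < 5:
        raise ValueError("total must be >= 5")
    weights = np.asarray(PAPER_CLASS_COUNTS, dtype=float)
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    for i in np.argsort(exact - counts)[::-1][: total - counts.sum()]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


# ---------------------------------------------------------------------------
# background and motif generation
# ---------------------------------------------------------------------------


def _sym_freqs(gc: float) -> tuple[float, float, float, float]:
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


def _spec_freqs(spec: LineageSpec, gc: float = 0.42) -> tuple[float, ...]:
    return spec.base_freqs if spec.base_freqs is not None else _sym_freqs(gc)


def _spec_coding(spec: LineageSpec, gc: float = 0.42) -> tuple[float, ...]:
    if spec.coding_freqs is not None:
        return spec.coding_freqs
    return _spec_freqs(spec, gc)


def _random_seq(rng: np.random.Generator, length: int,
                freqs: Sequence[float],
                forbidden: Sequence[str] = ()) -> str:
    """i.i.d. background; rejection-sampled so no forbidden motif occurs."""
    if length <= 0:
        return ""
    p = np.asarray(freqs, dtype=float)
    p = p / p.sum()
    for _ in range(100):
        codes = rng.choice(4, size=length, p=p)
        seq = _BASES[codes].tobytes().decode()
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError("could not sample motif-free background")


def _substring_clash(cand: str, accepted: Iterable[str]) -> bool:
    return any(cand in m or m in cand for m in accepted)


def make_lineage_library(n_lineages_per_superfamily: int, seed: int,
                         tir_motif: str = DEFAULT_TIR_MOTIF) -> list[LineageSpec]:
    """Build ``2 x n`` lineage specs (n Gypsy + n Copia) with pairwise
    non-overlapping domain motifs (no motif is a substring of another, nor
    of the TIR pair) and distinct, literature-style length ranges.
    Deterministic for a fixed seed.
    """
    if n_lineages_per_superfamily < 1:
        raise ValueError("need at least one lineage per superfamily")
    rng = np.random.default_rng(seed)
    accepted: list[str] = [tir_motif, reverse_complement(tir_motif)]
    specs: list[LineageSpec] = []
    for sf, prefix in ((Superfamily.GYPSY, "RLG"), (Superfamily.COPIA, "RLC")):
        for i in range(n_lineages_per_superfamily):
            name = f"{prefix}_{chr(ord('A') + i % 26)}{i // 26 or ''}"
            motifs: list[str] = []
            while len(motifs) < 5:
                mlen = int(rng.integers(18, 31))
                cand = _BASES[rng.choice(4, size=mlen)].tobytes().decode()
                if not _substring_clash(cand, accepted) and cand not in motifs:
                    motifs.append(cand)
                    accepted.append(cand)
            ltr_lo = int(rng.integers(150, 400))
            ltr_hi = ltr_lo + int(rng.integers(50, 250))
            tot_lo = int(rng.integers(4000, 7001))
            tot_hi = tot_lo + int(rng.integers(1500, 4001))
            def _draw_freqs():
                gc = float(rng.uniform(0.34, 0.56))
                c_share = float(rng.uniform(0.35, 0.65))
                a_share = float(rng.uniform(0.35, 0.65))
                return (a_share * (1 - gc), c_share * gc,
                        (1 - c_share) * gc, (1 - a_share) * (1 - gc))

            freqs = _draw_freqs()
            coding = _draw_freqs()
            specs.append(LineageSpec(
                name=name,
                superfamily=sf,
                ltr_len_range=(ltr_lo, ltr_hi),
                total_len_range=(tot_lo, tot_hi),
                domain_motifs=tuple(zip(DOMAIN_ORDER[sf], motifs)),
                base_freqs=freqs,
                coding_freqs=coding,
            ))
    return specs


def _all_motifs(library: Sequence[LineageSpec], tir_motif: str | None = None) -> list[str]:
    out = [m for spec in library for m in spec.motifs]
    if tir_motif:
        out += [tir_motif, reverse_complement(tir_motif)]
    return out


# ---------------------------------------------------------------------------
# element construction
# ---------------------------------------------------------------------------

_MIN_GAP = 10  # background spacer either side of each domain body

#: fraction of the internal region (after minimum gaps) occupied by the
#: five coding domain bodies; LTR-RT internals are mostly coding
_CODING_FRACTION = 0.6


def _build_element(spec: LineageSpec, rng: np.random.Generator, total: int,
                   freqs: Sequence[float], forbidden: Sequence[str]) -> tuple[str, int]:
    """Assemble LTR + internal + identical LTR of exactly ``total`` bp.

    The internal region carries the five domain bodies in superfamily
    order, each a coding-composition segment with its diagnostic motif
    embedded at a random offset, separated by intergenic background.
    Returns (sequence, ltr_len)."""
    lo, hi = spec.ltr_len_range
    ltr_len = int(rng.integers(lo, hi + 1))
    internal = total - 2 * ltr_len
    avail = internal - 6 * _MIN_GAP
    motif_lens = [len(m) for m in spec.motifs]
    if avail < sum(motif_lens):
        raise ValueError(f"total length {total} too short for {spec.name}")
    coding = _spec_coding(spec)
    weights = rng.dirichlet(np.full(5, 8.0))
    body_lens = np.maximum(motif_lens,
                           (weights * _CODING_FRACTION * avail).astype(int))
    while body_lens.sum() > avail:  # pathological short elements
        body_lens = np.maximum(motif_lens, body_lens - 10)
        if (body_lens == motif_lens).all():
            break
    spare = int(avail - body_lens.sum())
    cuts = np.sort(rng.integers(0, spare + 1, size=5))
    gaps = np.diff(np.concatenate(([0], cuts, [spare]))) + _MIN_GAP
    ltr = _random_seq(rng, ltr_len, freqs, forbidden)
    parts = [ltr]
    for gap, motif, blen in zip(gaps[:-1], spec.motifs, body_lens):
        parts.append(_random_seq(rng, int(gap), freqs, forbidden))
        offset = int(rng.integers(0, blen - len(motif) + 1))
        parts.append(_random_seq(rng, offset, coding, forbidden))
        parts.append(motif)
        parts.append(_random_seq(rng, int(blen) - len(motif) - offset,
                                 coding, forbidden))
    parts.append(_random_seq(rng, int(gaps[-1]), freqs, forbidden))
    parts.append(ltr)
    seq = "".join(parts)
    assert len(seq) == total
    return seq, ltr_len


def _draw_total(spec: LineageSpec, rng: np.random.Generator) -> int:
    return int(rng.integers(spec.total_len_range[0], spec.total_len_range[1] + 1))


def simulate_intact(spec: LineageSpec, rng: np.random.Generator, *,
                    gc: float = 0.42, forbidden: Sequence[str] = (),
                    seq_id: str = "intact") -> SequenceRecord:
    """One intact element: identical LTRs, the five lineage motifs exactly
    once each in superfamily order, total length inside ``total_len_range``.
    """
    total = _draw_total(spec, rng)
    seq, ltr = _build_element(spec, rng, total, _spec_freqs(spec, gc),
                              forbidden or spec.motifs)
    return SequenceRecord(seq_id, seq, f"class=0 lineage={spec.name} ltr={ltr}")


def simulate_nested(host: LineageSpec, donor: LineageSpec,
                    rng: np.random.Generator, *, gc: float = 0.42,
                    forbidden: Sequence[str] = (),
                    seq_id: str = "nested") -> tuple[SequenceRecord, int]:
    """Insert a full donor element at a uniform position strictly inside the
    host's internal region.  Returns the record and its ground-truth label:
    1 when the superfamilies differ, 2 for same superfamily but different
    lineage."""
    if host.name == donor.name:
        raise ValueError("host and donor must be different lineages")
    fb = forbidden or _all_motifs([host, donor])
    host_total = _draw_total(host, rng)
    host_seq, host_ltr = _build_element(host, rng, host_total,
                                        _spec_freqs(host, gc), fb)
    donor_total = _draw_total(donor, rng)
    donor_seq, _ = _build_element(donor, rng, donor_total,
                                  _spec_freqs(donor, gc), fb)
    pos = int(rng.integers(host_ltr + 1, host_total - host_ltr))
    seq = host_seq[:pos] + donor_seq + host_seq[pos:]
    label = 1 if host.superfamily != donor.superfamily else 2
    note = (f"class={label} host={host.name} donor={donor.name} pos={pos} "
            f"host_len={host_total} donor_len={donor_total}")
    return SequenceRecord(seq_id, seq, note), label


def simulate_length_anomaly(spec: LineageSpec, rng: np.random.Generator, *,
                            gc: float = 0.42, forbidden: Sequence[str] = (),
                            factor_range: tuple[float, float] = (1.22, 1.40),
                            seq_id: str = "anomaly") -> SequenceRecord:
    """Single-lineage element whose total length exceeds the lineage range
    maximum by more than the curation tolerance (padding is motif-free
    background inside the internal region)."""
    factor = rng.uniform(*factor_range)
    total = int(np.ceil(spec.total_len_range[1] * factor))
    seq, ltr = _build_element(spec, rng, total, _spec_freqs(spec, gc),
                              forbidden or spec.motifs)
    return SequenceRecord(seq_id, seq, f"class=3 lineage={spec.name} ltr={ltr}")


def simulate_class2_insertion(spec: LineageSpec, config: SimConfig,
                              rng: np.random.Generator, *,
                              forbidden: Sequence[str] = (),
                              seq_id: str = "class2") -> SequenceRecord:
    """Intact element plus one TIR-flanked segment (motif, spacer, reverse
    complement) in the internal region; total stays within the ±tolerance
    band so only the Class II filter fires."""
    tir = config.tir_motif
    fb = list(forbidden or spec.motifs) + [tir, reverse_complement(tir)]
    tot_lo, tot_hi = spec.total_len_range
    limit = int(tot_hi * (1 + config.length_tolerance))
    # clamp the insert so even the shortest host stays within the band
    budget = limit - tot_lo - 2 * len(tir)
    if budget < 10:
        raise ValueError("length band too narrow for a Class II insertion")
    lo, hi = config.class2_insert_len_range
    hi = min(hi, budget)
    lo = min(lo, hi)
    interior = _random_seq(rng, int(rng.integers(lo, hi + 1)),
                           config.class2_base_freqs, fb)
    insert = tir + interior + reverse_complement(tir)
    total = int(rng.integers(tot_lo, min(tot_hi, limit - len(insert)) + 1))
    seq, ltr = _build_element(spec, rng, total, _spec_freqs(spec), fb)
    if total + len(insert) > limit:
        raise ValueError("insertion would trip the length filter")
    pos = int(rng.integers(ltr + 1, total - ltr))
    seq = seq[:pos] + insert + seq[pos:]
    note = f"class=4 lineage={spec.name} pos={pos} insert_len={len(insert)}"
    return SequenceRecord(seq_id, seq, note)


# ---------------------------------------------------------------------------
# dataset assembly and I/O
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig, library: Sequence[LineageSpec]) -> LabeledDataset:
    """Simulate ``n_per_class[c]`` records per class ``c`` and shuffle them
    deterministically by the config seed."""
    if not library:
        raise ValueError("lineage library must be non-empty")
    motifs = _all_motifs(library, config.tir_motif)
    if any(_substring_clash(m, [o for o in motifs if o is not m]) for m in motifs):
        raise ValueError("library motifs overlap (substring clash)")
    by_sf: dict[Superfamily, list[LineageSpec]] = {}
    for spec in library:
        by_sf.setdefault(spec.superfamily, []).append(spec)
    n0, n1, n2, n3, n4 = config.n_per_class
    if n1 > 0 and len(by_sf) < 2:
        raise ValueError("class 1 needs both superfamilies in the library")
    if n2 > 0 and not any(len(v) >= 2 for v in by_sf.values()):
        raise ValueError("class 2 needs >= 2 lineages in one superfamily")

    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    records: list[SequenceRecord] = []
    labels: list[int] = []

    def pick(specs: Sequence[LineageSpec]) -> LineageSpec:
        return specs[int(rng.integers(len(specs)))]

    for _ in range(n0):
        records.append(simulate_intact(pick(library), rng, gc=gc, forbidden=motifs))
        labels.append(0)
    for _ in range(n1):
        sfs = list(by_sf)
        a, b = rng.permutation(len(sfs))[:2]
        rec, label = simulate_nested(pick(by_sf[sfs[a]]), pick(by_sf[sfs[b]]),
                                     rng, gc=gc, forbidden=motifs)
        assert label == 1
        records.append(rec)
        labels.append(1)
    pools = [v for v in by_sf.values() if len(v) >= 2]
    for _ in range(n2):
        pool = pools[int(rng.integers(len(pools)))]
        i, j = rng.permutation(len(pool))[:2]
        rec, label = simulate_nested(pool[i], pool[j], rng, gc=gc, forbidden=motifs)
        assert label == 2
        records.append(rec)
        labels.append(2)
    for _ in range(n3):
        records.append(simulate_length_anomaly(
            pick(library), rng, gc=gc, forbidden=motifs,
            factor_range=config.anomaly_factor_range))
        labels.append(3)
    for _ in range(n4):
        records.append(simulate_class2_insertion(pick(library), config, rng,
                                                 forbidden=motifs))
        labels.append(4)

    order = rng.permutation(len(records))
    width = max(5, len(str(len(records))))
    out_records, out_labels, out_prov = [], [], []
    for rank, idx in enumerate(order):
        rec = records[idx]
        out_records.append(dataclasses.replace(rec, id=f"seq_{rank:0{width}d}"))
        out_labels.append(labels[idx])
        out_prov.append(rec.description)
    return LabeledDataset(out_records, out_labels, out_prov)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Multi-FASTA wrapped at 60 columns."""
    recs = [SeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    return out


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    """Two-column TSV: seq_id<TAB>label."""
    with open(path, "w") as fh:
        for rec, label in zip(dataset.records, dataset.labels):
            fh.write(f"{rec.id}\t{label}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sid, lab = line.rstrip("\n").split("\t")[:2]
                out[sid] = int(lab)
    return out


def library_to_yaml(library: Sequence[LineageSpec], path: str | Path) -> None:
    data = [{
        "name": s.name,
        "superfamily": s.superfamily.value,
        "ltr_len_range": list(s.ltr_len_range),
        "total_len_range": list(s.total_len_range),
        "domain_motifs": [[d, m] for d, m in s.domain_motifs],
        "base_freqs": list(s.base_freqs) if s.base_freqs else None,
        "coding_freqs": list(s.coding_freqs) if s.coding_freqs else None,
    } for s in library]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def library_from_yaml(path: str | Path) -> list[LineageSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [LineageSpec(
        name=d["name"],
        superfamily=Superfamily(d["superfamily"]),
        ltr_len_range=tuple(d["ltr_len_range"]),
        total_len_range=tuple(d["total_len_range"]),
        domain_motifs=tuple((a, b) for a, b in d["domain_motifs"]),
        base_freqs=tuple(d["base_freqs"]) if d.get("base_freqs") else None,
        coding_freqs=tuple(d["coding_freqs"]) if d.get("coding_freqs") else None,
    ) for d in data]
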