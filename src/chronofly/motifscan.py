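"""IUPAC cis-motif counting and observed/expected enrichment in promoters.

Occurrences of degenerate consensus motifs (E-box, D-box, RRE, ...) are
counted on both strands of a promoter region, overlapping matches included.
The expected count under a random-sequence background is

    strands * (L - k + 1) * sum over concrete words of prod_j p(base_j)

and the fold enrichment is observed/expected, the observed-over-random
ratio used to compare promoters between species.  A fold of 1 means the
motif occurs exactly as often as chance predicts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

#: Motifs with a printed consensus plus common literature consensi for the
#: remaining circadian elements; all user-overridable.
DEFAULT_MOTIFS = {
    "E-box": "CACGTG",
    "E-box-like_CACGTH": "CACGTH",
    "E-box-like_AACGTG": "AACGTG",
    "D-box": "TTATGTAA",
}


@dataclass(frozen=True)
class Motif:
    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        for i, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC:
                raise ValueError(
                    f"motif {self.name!r}: illegal IUPAC character {ch!r} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def reverse_complement(self) -> str:
        return self.iupac.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRegion:
    """A promoter piece: upstream-of-ATG (``ups``) or upstream plus first
    intron (``ups_plus``).

    ``parts`` carries non-contiguous pieces (upstream sequence, first
    intron); matches never span the junction because the pieces are not
    adjacent genomic DNA.  ``sequence`` is their concatenation.
    """

    gene: str
    species: str
    region_kind: str
    parts: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = tuple(p.upper() for p in self.parts)
        for p in parts:
            if re.search(r"[^ACGTN]", p):
                raise ValueError(
                    f"{self.gene}/{self.region_kind}: sequence letters must be "
                    f"A/C/G/T/N"
                )
        self.parts = parts

    @classmethod
    def from_sequence(cls, gene: str, species: str, region_kind: str,
                      sequence: str) -> "PromoterRegion":
        return cls(gene, species, region_kind, (sequence,))

    @property
    def sequence(self) -> str:
        return "".join(self.parts)

    @property
    def length_bp(self) -> int:
        return sum(len(p) for p in self.parts)

    @property
    def label(self) -> str:
        return f"{self.gene}|{self.species}|{self.region_kind}"


@dataclass
class MotifEnrichment:
    region: PromoterRegion
    motif: Motif
    observed: int
    expected: float
    fold: float
    positions: list[tuple[int, str]] = field(default_factory=list)


def expand_iupac(motif: Motif | str) -> tuple[int, list[str]]:
    """Degeneracy of a consensus: (word count, per-position allowed bases).

    The word count is the product of the per-position set sizes, e.g. 3 for
    CACGTH (H = A/C/T).
    """
    iupac = motif.iupac if isinstance(motif, Motif) else Motif("m", motif).iupac
    sets = [IUPAC[ch] for ch in iupac.upper()]
    count = 1
    for s in sets:
        count *= len(s)
    return count, sets


def expand_words(motif: Motif | str) -> list[str]:
    """All concrete A/C/G/T words matching the consensus."""
    _, sets = expand_iupac(motif)
    return ["".join(w) for w in product(*sets)]


def _motif_regex(iupac: str) -> re.Pattern:
    # lookahead makes overlapping matches visible
    body = "".join(
        b if len(b := IUPAC[ch]) == 1 else f"[{b}]" for ch in iupac.upper()
    )
    return re.compile(f"(?=({body}))")


def count_occurrences(region: PromoterRegion,
                      motif: Motif) -> tuple[int, list[tuple[int, str]]]:
    """Count motif sites on both strands, overlapping matches included.

    Positions are 0-based forward-strand coordinates of each site's 5'
    end: the leftmost base for a plus-strand site, the rightmost for a
    minus-strand site (where the motif reads 5'->3' on the complement).
    A palindromic site therefore yields one hit per strand.  ``N`` bases
    never match.  A motif longer than the region gives zero hits.
    """
    k = len(motif)
    positions: list[tuple[int, str]] = []
    fwd = _motif_regex(motif.iupac)
    rev = _motif_regex(motif.reverse_complement)
    offset = 0
    for part in region.parts:
        for m in fwd.finditer(part):
            positions.append((offset + m.start(), "+"))
        for m in rev.finditer(part):
            positions.append((offset + m.start() + k - 1, "-"))
        offset += len(part)
    positions.sort()
    return len(positions), positions


def _word_probability(sets: Sequence[str], background: dict[str, float]) -> float:
    # independence lets the sum over words factor into per-position sums
    p = 1.0
    for s in sets:
        p *= sum(background[b] for b in s)
    return p


def expected_count(length_bp: int, motif: Motif,
                   background: dict[str, float] | None = None,
                   strands: int = 2,
                   region: PromoterRegion | None = None) -> float:
    """Expected number of motif sites in random DNA of the given length.

    ``strands * (L - k + 1)`` scannable offsets times the probability that
    a random word matches the consensus under the background base
    composition (uniform by default).  When a region is supplied, offsets
    whose window contains an ``N`` are subtracted and multi-part regions
    contribute ``L_part - k + 1`` offsets per part (junctions are not
    scannable).
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    if abs(sum(background.values()) - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    k = len(motif)
    if k == 0:
        raise ValueError("zero-length motif")
    if strands not in (1, 2):
        raise ValueError("strands must be 1 or 2")
    _, sets = expand_iupac(motif)
    p_fwd = _word_probability(sets, background)
    if strands == 2:
        comp_sets = [s.translate(_COMPLEMENT) for s in sets]
        p = p_fwd + _word_probability(comp_sets, background)
    else:
        p = p_fwd
    if region is not None:
        n_offsets = 0
        for part in region.parts:
            if len(part) < k:
                continue
            has_n = np.frombuffer(part.encode(), dtype=np.uint8) == ord("N")
            if has_n.any():
                window_n = np.convolve(has_n.astype(int), np.ones(k, dtype=int),
                                       mode="valid")
                n_offsets += int((window_n == 0).sum())
            else:
                n_offsets += len(part) - k + 1
    else:
        if length_bp < k:
            raise ValueError(f"region of {length_bp} bp shorter than {k}-bp motif")
        n_offsets = length_bp - k + 1
    return n_offsets * p


def fold_enrichment(observed: int, expected: float) -> float:
    """Observed/expected ratio; 1 = chance level."""
    if expected <= 0:
        raise ValueError(f"expected count must be > 0, got {expected}")
    return observed / expected


def enrichment_table(regions: Sequence[PromoterRegion], motifs: Sequence[Motif],
                     background: dict[str, float] | None = None,
                     strands: int = 2) -> pd.DataFrame:
    """One row per (region, motif) with observed, expected and fold values.

    Pass ``background=None`` for the uniform random-DNA model, or a base
    probability dict (e.g. the observed composition) for a sensitivity
    analysis.  Duplicate (gene, species, region_kind) keys are rejected.
    """
    if not regions or not motifs:
        raise ValueError("need at least one region and one motif")
    keys = [(r.gene, r.species, r.region_kind) for r in regions]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate region keys: {dupes}")
    rows = []
    for r in regions:
        for m in motifs:
            obs, pos = count_occurrences(r, m)
            exp = expected_count(r.length_bp, m, background=background,
                                 strands=strands, region=r)
            rows.append({
                "gene": r.gene, "species": r.species,
                "region_kind": r.region_kind, "motif": m.name,
                "iupac": m.iupac, "length_bp": r.length_bp,
                "observed": obs, "expected": exp,
                "fold": obs / exp if exp > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def position_map(region: PromoterRegion, motifs: Sequence[Motif],
                 exclude: Iterable[str] = ()) -> pd.DataFrame:
    """Coordinate-sorted site annotations for drawing promoter maps.

    Intervals are 0-based half-open on the forward strand.  ``exclude``
    drops motifs by name (e.g. E-boxes on crowded maps).  The sort is by
    (start, end, motif name, strand) and therefore stable under any input
    motif order.
    """
    excluded = set(exclude)
    rows = []
    for m in motifs:
        if m.name in excluded:
            continue
        k = len(m)
        _, positions = count_occurrences(region, m)
        for pos, strand in positions:
            start = pos if strand == "+" else pos - k + 1
            rows.append({"motif": m.name, "start": start, "end": start + k,
                         "strand": strand})
    df = pd.DataFrame(rows, columns=["motif", "start", "end", "strand"])
    return df.sort_values(["start", "end", "motif", "strand"],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_promoter_fasta(path) -> list[PromoterRegion]:
    """Read promoter regions from FASTA with ``>gene|species|region_kind``
    headers.

    Records sharing a (gene, species, region_kind) key become the ordered
    parts of one multi-part region (upstream piece plus first intron for
    ``ups_plus``).
    """
    grouped: dict[tuple[str, str, str], list[str]] = {}
    order: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 3:
            raise ValueError(
                f"FASTA header {rec.id!r} is not gene|species|region_kind"
            )
        key = (fields[0], fields[1], fields[2])
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(str(rec.seq))
    if not order:
        raise ValueError(f"{path}: no FASTA records")
    return [
        PromoterRegion(gene=g, species=s, region_kind=rk,
                       parts=tuple(grouped[(g, s, rk)]))
        for g, s, rk in order
    ]


def read_motif_config(path) -> list[Motif]:
    """Read ``name = IUPAC`` motif definitions, one per line, # comments."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'name = IUPAC'")
            name, iupac = (part.strip() for part in line.split("=", 1))
            motifs.append(Motif(name, iupac))
    if not motifs:
        raise ValueError(f"{path}: no motif definitions")
    return motifs


def default_motifs() -> list[Motif]:
    return [Motif(n, i) for n, i in DEFAULT_MOTIFS.items()]


def observed_background(region: PromoterRegion) -> dict[str, float]:
    """Base composition of a region (N excluded), for sensitivity analysis."""
    seq = region.sequence.replace("N", "")
    if not seq:
        raise ValueError("region has no unambiguous bases")
    return {b: seq.count(b) / len(seq) for b in "ACGT"}


def write_position_bed(region: PromoterRegion, annotations: pd.DataFrame,
                       path) -> None:
    """Write a BED-like file: region label, start, end, motif, score, strand."""
    with open(path, "w") as fh:
        for row in annotations.itertuples(index=False):
            fh.write(f"{region.label}\t{row.start}\t{row.end}\t{row.motif}\t.\t{row.strand}\n")
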