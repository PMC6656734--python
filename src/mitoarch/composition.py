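"""Per-taxon nucleotide composition, strand asymmetry and codon usage.

All whole-molecule statistics are computed on the forward (deposited)
strand. Assembly gaps (runs of N) are excluded from every denominator so a
gapped control region cannot bias AT%. Codon statistics use the
invertebrate mitochondrial genetic code (NCBI translation table 5:
AGA/AGG = Ser, ATA = Met, TGA = Trp).

* AT% = 100 (A+T)/(A+C+G+T)
* AT-skew = (A-T)/(A+T),  GC-skew = (G-C)/(G+C)
* SUskew = (L+ - L-)/(L+ + L-) over summed annotated gene lengths per strand
* UR% = 100 x (genome length - union of annotated feature spans) / length
* RSCU(c) = count(c) / (family total / family size), sense codons only
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import GeneFeature, MitogenomeRecord

logger = logging.getLogger(__name__)

#: NCBI translation table 5 — invertebrate mitochondrial
INVERT_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]

#: codon -> amino acid over the 62 sense codons of table 5
CODON_TO_AA: dict[str, str] = dict(INVERT_MITO_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(INVERT_MITO_TABLE.stop_codons)

#: amino acid -> synonymous codon family (sorted)
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_FAMILIES.setdefault(_aa, ())
    AA_FAMILIES[_aa] = AA_FAMILIES[_aa] + (_codon,)


@dataclass
class CompositionProfile:
    taxon_id: str
    at_percent: float
    at_skew: float | None
    gc_skew: float | None
    su_skew: float
    ur_percent: float
    codon_counts: dict[str, int] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)
    aa_freq: dict[str, float] = field(default_factory=dict)


def base_composition(record: MitogenomeRecord) -> tuple[float, float | None, float | None]:
    """(AT%, AT-skew, GC-skew) on the forward strand; N runs excluded."""
    seq = record.sequence.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    total = a + c + g + t
    if total == 0:
        raise ValueError(f"{record.taxon_id}: sequence has no unambiguous bases")
    at_percent = 100.0 * (a + t) / total
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    if at_skew is None or gc_skew is None:
        logger.warning("%s: skew undefined (missing base class)", record.taxon_id)
    return at_percent, at_skew, gc_skew


def unassigned_fraction(record: MitogenomeRecord) -> float:
    """Percentage of the molecule covered by no annotated gene feature.

    Overlaps count once (interval union); the control region, never being an
    annotated gene, contributes to the unassigned fraction.
    """
    if not record.features:
        raise ValueError(f"{record.taxon_id}: no features")
    ivals: list[tuple[int, int]] = []
    for ft in record.features:
        ivals.extend(ft.intervals(record.length))
    ivals.sort()
    covered = 0
    cur_start, cur_end = ivals[0]
    for s, e in ivals[1:]:
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start
    return 100.0 * (record.length - covered) / record.length


def strand_usage_skew(record: MitogenomeRecord) -> float:
    """(L+ - L-)/(L+ + L-) over summed annotated gene lengths per strand."""
    plus = sum(ft.length(record.length) for ft in record.features if ft.strand > 0)
    minus = sum(ft.length(record.length) for ft in record.features if ft.strand < 0)
    if plus + minus == 0:
        raise ValueError(f"{record.taxon_id}: no annotated features")
    return (plus - minus) / (plus + minus)


def codon_usage(record: MitogenomeRecord) -> dict[str, int]:
    """Codon counts over all protein-coding genes, 5'->3' on the coding strand.

    The initiation codon is counted as given; the terminal stop codon and any
    trailing incomplete codon (polyadenylation-completed stops) are excluded.
    Internal stops are flagged as possible annotation errors but counted.
    """
    pcgs = [ft for ft in record.features if ft.kind == "PCG"]
    if not any(ft.length(record.length) >= 6 for ft in pcgs):
        raise ValueError(f"{record.taxon_id}: no usable protein-coding feature")
    counts: dict[str, int] = {}
    for ft in pcgs:
        cds = record.feature_sequence(ft).upper()
        n_codons = len(cds) // 3
        codons = [cds[3 * i: 3 * i + 3] for i in range(n_codons)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                logger.warning(
                    "%s: internal stop codon %s in %s at codon %d "
                    "(possible annotation error)",
                    record.taxon_id, codon, ft.token, idx,
                )
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu(codon_counts: Mapping[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    rscu(c) = count(c) / (family total / family size); families with zero
    total are omitted. Per family, values average to 1 by construction.
    """
    out: dict[str, float] = {}
    for aa, family in AA_FAMILIES.items():
        total = sum(codon_counts.get(c, 0) for c in family)
        if total == 0:
            continue
        expected = total / len(family)
        for c in family:
            out[c] = codon_counts.get(c, 0) / expected
    return out


def amino_acid_frequencies(codon_counts: Mapping[str, int]) -> dict[str, float]:
    totals: dict[str, int] = {}
    for codon, n in codon_counts.items():
        aa = CODON_TO_AA.get(codon)
        if aa is not None:
            totals[aa] = totals.get(aa, 0) + n
    grand = sum(totals.values())
    return {aa: n / grand for aa, n in sorted(totals.items())} if grand else {}


def composition_profile(record: MitogenomeRecord) -> CompositionProfile:
    at_percent, at_skew, gc_skew = base_composition(record)
    counts = codon_usage(record)
    return CompositionProfile(
        taxon_id=record.taxon_id,
        at_percent=at_percent,
        at_skew=at_skew,
        gc_skew=gc_skew,
        su_skew=strand_usage_skew(record),
        ur_percent=unassigned_fraction(record),
        codon_counts=counts,
        rscu=rscu(counts),
        aa_freq=amino_acid_frequencies(counts),
    )


def profiles_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Fixed-column per-taxon profile table (one row per taxon)."""
    rows = [
        {
            "taxon_id": p.taxon_id,
            "at_percent": p.at_percent,
            "at_skew": p.at_skew,
            "gc_skew": p.gc_skew,
            "su_skew": p.su_skew,
            "ur_percent": p.ur_percent,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["taxon_id", "at_percent", "at_skew",
                                       "gc_skew", "su_skew", "ur_percent"])


def codon_long_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Long-format (taxon, codon, aa, count, rscu) table."""
    rows = []
    for p in profiles:
        for codon in sorted(p.rscu):
            rows.append({
                "taxon_id": p.taxon_id,
                "codon": codon,
                "aa": CODON_TO_AA[codon],
                "count": p.codon_counts.get(codon, 0),
                "rscu": p.rscu[codon],
            })
    return pd.DataFrame(rows, columns=["taxon_id", "codon", "aa", "count", "rscu"])
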