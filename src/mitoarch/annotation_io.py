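"""Read annotated mitogenomes, normalise gene nomenclature, write tables.

GenBank deposits are notoriously inconsistent — gene labels vary (COI vs
COX1 vs "cytochrome oxidase subunit I"), strands are occasionally wrong and
genes go missing — so the reader normalises every feature name against a
shipped synonym table and reports diagnostics (missing canonical genes,
unknown labels, duplicated tokens) instead of failing or silently dropping.

Internal coordinates are 0-based half-open on the forward strand; conversion
to/from GenBank's 1-based inclusive convention happens only at this
boundary. Features written across the origin of the circular molecule (join
notation) are flagged ``spans_origin``.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import vocab
from .gene_orders import (
    GeneOrder,
    MGOPattern,
    format_order_string,
    parse_order_string,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-name normalisation
# ---------------------------------------------------------------------------

def _load_name_table() -> dict[str, str]:
    text = resources.files("mitoarch.data").joinpath("gene_names.tsv").read_text()
    rows = csv.DictReader(text.splitlines(), delimiter="\t")
    return {row["raw"].strip().lower(): row["token"].strip() for row in rows}


_NAME_TABLE = _load_name_table()

_TRNA_RE = re.compile(
    r"^(?:trn|trna[-_ ]?)"
    r"(?P<aa>[a-z]{3}|[acdefghiklmnpqrstvwy])"
    r"(?P<iso>[12])?"
    r"(?:\s*\(\s*(?P<anticodon>[acgtu]{3})\s*\))?$"
)


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a raw gene/product label to one of the 40 canonical tokens.

    Case-insensitive and synonym-aware via the shipped lookup table; tRNA
    labels are parsed for amino acid, an explicit 1/2 isoacceptor index, or
    an anticodon tag (Leu and Ser need one of the latter two). Unresolvable
    labels map to the sentinel ``unknown`` — reported, never dropped.
    Idempotent: normalised tokens map to themselves.
    """
    label = (raw or "").strip()
    if not label:
        return vocab.UNKNOWN
    if label in vocab.ALL_TOKENS:  # already normalised (tokens are case-sensitive)
        return label
    low = label.lower()
    if low in _NAME_TABLE:
        return _NAME_TABLE[low]
    m = _TRNA_RE.match(low)
    if m:
        aa_raw = m.group("aa")
        aa = vocab.AA3_TO_1.get(aa_raw, aa_raw.upper() if len(aa_raw) == 1 else None)
        if aa is None:
            return vocab.UNKNOWN
        anti = (m.group("anticodon") or anticodon or "").lower().replace("u", "t")
        if aa in ("L", "S"):
            if m.group("iso"):
                return f"trn{aa}{m.group('iso')}"
            if (aa, anti) in vocab.LEU_SER_ANTICODONS:
                return vocab.LEU_SER_ANTICODONS[(aa, anti)]
            return vocab.UNKNOWN  # ambiguous isoacceptor, reported upstream
        token = f"trn{aa}"
        return token if token in vocab.TRNA_TOKENS else vocab.UNKNOWN
    return vocab.UNKNOWN


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circular molecule (internal coordinates)."""

    token: str
    kind: str  # PCG | rRNA | tRNA | other
    strand: int  # +1 / -1
    start: int  # 0-based
    end: int  # half-open; end <= start only when spans_origin
    spans_origin: bool = False

    def length(self, genome_length: int) -> int:
        if self.spans_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        if self.spans_origin:
            return [(self.start, genome_length), (0, self.end)]
        return [(self.start, self.end)]


@dataclass
class MitogenomeRecord:
    """A complete annotated mitogenome plus reader diagnostics."""

    taxon_id: str
    sequence: str
    features: list[GeneFeature]
    group_labels: dict[str, str] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Feature sequence on its coding strand, 5'->3'."""
        if feat.spans_origin:
            raw = self.sequence[feat.start:] + self.sequence[: feat.end]
        else:
            raw = self.sequence[feat.start: feat.end]
        if feat.strand < 0:
            return str(Seq(raw).reverse_complement())
        return raw


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

_FEATURE_KINDS = {"CDS": "PCG", "rRNA": "rRNA", "tRNA": "tRNA", "misc_feature": "other",
                  "D-loop": "other"}


def _raw_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "label", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return ""


def read_genbank(path: str | Path, group_labels: Mapping[str, str] | None = None) -> MitogenomeRecord:
    """Parse one GenBank flat file into a :class:`MitogenomeRecord`.

    Diagnostics surface the inconsistencies curators usually fix by hand:
    canonical genes that are missing, labels that could not be normalised,
    and duplicated tokens. Raises on unparseable files and on files with no
    recognisable gene features (never silently empty).
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"{path}: not a readable GenBank flat file ({exc})") from exc

    taxon_id = seqrec.annotations.get("organism") or seqrec.name or path.stem
    taxon_id = taxon_id.replace(" ", "_")
    diagnostics: list[str] = []
    feats: list[GeneFeature] = []
    for f in seqrec.features:
        if f.type not in _FEATURE_KINDS or f.type in ("misc_feature", "D-loop"):
            continue
        raw = _raw_label(f)
        anticodon = None
        if f.qualifiers.get("anticodon"):
            m = re.search(r"seq\s*:\s*([a-zA-Z]{3})", str(f.qualifiers["anticodon"][0]))
            anticodon = m.group(1) if m else str(f.qualifiers["anticodon"][0])[-4:-1]
        token = normalize_gene_name(raw, anticodon=anticodon)
        if token == vocab.UNKNOWN:
            diagnostics.append(f"unknown gene label {raw!r} ({f.type})")
        kind = vocab.classify_token(token) if token != vocab.UNKNOWN else _FEATURE_KINDS[f.type]
        loc = f.location
        spans_origin = False
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            if len(parts) == 2 and int(parts[1].end) == len(seqrec.seq) and int(parts[0].start) == 0:
                spans_origin = True
                start, end = int(parts[1].start), int(parts[0].end)
            else:
                start, end = int(loc.start), int(loc.end)
                diagnostics.append(f"compound location on {token}: flattened to envelope")
        else:
            start, end = int(loc.start), int(loc.end)
        strand = -1 if (loc.strand or 1) < 0 else 1
        feats.append(GeneFeature(token=token, kind=kind, strand=strand,
                                 start=start, end=end, spans_origin=spans_origin))

    if not feats:
        raise ValueError(f"{path}: no recognisable gene features")

    counts: dict[str, int] = {}
    for ft in feats:
        if ft.token != vocab.UNKNOWN:
            counts[ft.token] = counts.get(ft.token, 0) + 1
    for tok, c in sorted(counts.items()):
        if c > 1:
            diagnostics.append(f"duplicated gene token {tok} (x{c})")
    for tok in sorted(vocab.ALL_TOKENS - set(counts)):
        diagnostics.append(f"missing canonical gene {tok}")

    for d in diagnostics:
        logger.warning("%s: %s", taxon_id, d)
    return MitogenomeRecord(
        taxon_id=taxon_id,
        sequence=str(seqrec.seq),
        features=feats,
        group_labels=dict(group_labels or {}),
        diagnostics=diagnostics,
    )


def read_genbank_dir(path: str | Path,
                     group_labels: Mapping[str, Mapping[str, str]] | None = None) -> list[MitogenomeRecord]:
    records = []
    for p in sorted(Path(path).glob("*.gb")) + sorted(Path(path).glob("*.gbk")):
        labels = (group_labels or {}).get(p.stem, {})
        records.append(read_genbank(p, group_labels=labels))
    return records


# ---------------------------------------------------------------------------
# GenBank writing (used by the synthetic generator; fixed date, so outputs
# are byte-stable under identical inputs)
# ---------------------------------------------------------------------------

def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.taxon_id[:16],
        name=record.taxon_id[:16],
        description=f"{record.taxon_id} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.taxon_id,
            "date": "01-JAN-2019",
        },
    )
    kind_to_type = {"PCG": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "other": "misc_feature"}
    L = record.length
    for ft in record.features:
        strand = 1 if ft.strand > 0 else -1
        if ft.spans_origin:
            loc = CompoundLocation([
                FeatureLocation(ft.start, L, strand=strand),
                FeatureLocation(0, ft.end, strand=strand),
            ])
        else:
            loc = FeatureLocation(ft.start, ft.end, strand=strand)
        sf = SeqFeature(loc, type=kind_to_type.get(ft.kind, "misc_feature"))
        sf.qualifiers["gene"] = [ft.token]
        sf.qualifiers["product"] = [ft.token]
        seqrec.features.append(sf)
    SeqIO.write(seqrec, str(path), "genbank")


def write_fasta(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.taxon_id}\n")
            for i in range(0, rec.length, 70):
                fh.write(rec.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# tabular writers / readers (deterministic; round-trip is the identity)
# ---------------------------------------------------------------------------

def write_gene_orders_tsv(orders: Sequence[GeneOrder], path: str | Path,
                          group_map: Mapping[str, str] | None = None) -> None:
    group_map = group_map or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["taxon_id", "group", "tokens"])
        for o in orders:
            w.writerow([o.taxon_id, group_map.get(o.taxon_id, ""), format_order_string(o.tokens)])


def read_gene_orders_tsv(path: str | Path) -> tuple[list[GeneOrder], dict[str, str]]:
    orders, groups = [], {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            orders.append(GeneOrder(taxon_id=row["taxon_id"],
                                    tokens=parse_order_string(row["tokens"])))
            if row.get("group"):
                groups[row["taxon_id"]] = row["group"]
    return orders, groups


def write_patterns_tsv(patterns: Sequence[MGOPattern], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pattern_id", "count", "exemplar", "members"])
        for p in patterns:
            w.writerow([p.pattern_id, p.count, format_order_string(p.exemplar.tokens),
                        ",".join(p.members)])


def read_patterns_tsv(path: str | Path) -> list[MGOPattern]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            members = tuple(row["members"].split(",")) if row["members"] else ()
            exemplar = GeneOrder(taxon_id=members[0] if members else "",
                                 tokens=parse_order_string(row["exemplar"]))
            out.append(MGOPattern(pattern_id=row["pattern_id"], exemplar=exemplar,
                                  members=members))
    return out


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tables(objects: Mapping[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline product it recognises into ``out_dir``.

    Keys select the writer: ``gene_orders``, ``patterns``, ``profiles``
    (a pandas DataFrame), ``hermes`` (a dict), ``scenarios`` (list of
    Scenario). Returns the map of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, obj in objects.items():
        if key == "gene_orders":
            p = out_dir / "gene_orders.tsv"
            write_gene_orders_tsv(obj, p)
        elif key == "patterns":
            p = out_dir / "patterns.tsv"
            write_patterns_tsv(obj, p)
        elif key == "profiles":
            p = out_dir / "profiles.tsv"
            obj.to_csv(p, sep="\t", index=False)
        elif key == "hermes":
            p = out_dir / "hermes.json"
            write_json(obj, p)
        elif key == "scenarios":
            p = out_dir / "scenarios.json"
            write_json([s.to_dict() for s in obj], p)
        else:
            raise ValueError(f"write_tables does not know how to write {key!r}")
        written[key] = p
    return written
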