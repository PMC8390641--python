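"""Transcript exon structures and the derived exon-exon junction catalog.

A locus is described by a set of transcript models, exactly one of which is the
*main* (predominant) isoform.  Every pair of adjacent exons in every transcript
defines a genomic junction ``(chrom, donor_end, acceptor_start)`` where
``donor_end`` is the last base of the upstream-in-genome exon and
``acceptor_start`` the first base of the downstream-in-genome exon (1-based,
inclusive, strand-agnostic: spliced aligners report skip boundaries in genome
coordinates regardless of transcription strand).

Junctions are classified relative to the main isoform:

``main``
    present in the main transcript.
``cterm_distinct``
    the pair of junctions shared by all C-terminal (beta-family) alternative
    transcripts and absent from the main isoform; their read counts are
    averaged by the downstream exonic-fraction statistic.
``utr5_distinct``
    the 5'UTR alternative-acceptor junction that differs from a main junction
    by exactly 3 bases on one boundary.
``gamma_distinct``
    junctions found exclusively in gamma-family transcripts.
``other_distinct``
    any remaining non-main junction (e.g. alternative 5' starts shared
    between beta- and gamma-family transcripts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputDataError, ModelValidationError

KLASS_MAIN = "main"
KLASS_CTERM = "cterm_distinct"
KLASS_UTR5 = "utr5_distinct"
KLASS_GAMMA = "gamma_distinct"
KLASS_OTHER = "other_distinct"

#: roles a transcript may play in junction classification (besides main/alternative)
JUNCTION_ROLES = ("cterm", "utr5", "gamma")

MAIN_ROLE = "main"
ALT_ROLE = "alternative"


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon, 1-based inclusive coordinates.

    ``exon_index`` is the ordinal in the transcript's own 5'->3' order (the
    convention used when naming junctions such as "exon 9 - exon 10" of a
    particular isoform); on the minus strand exon 1 has the highest genomic
    coordinates.
    """

    chrom: str
    start: int
    end: int
    exon_index: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelValidationError(
                f"exon start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.exon_index < 1:
            raise ModelValidationError("exon_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered (5'->3') tuple of non-overlapping exons."""

    transcript_id: str
    strand: str
    exons: tuple[Exon, ...]
    role: str = ALT_ROLE
    junction_role: str | None = None  # one of JUNCTION_ROLES, or None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"bad strand {self.strand!r}")
        if self.role not in (MAIN_ROLE, ALT_ROLE):
            raise ModelValidationError(f"bad role {self.role!r}")
        if self.junction_role is not None and self.junction_role not in JUNCTION_ROLES:
            raise ModelValidationError(f"bad junction_role {self.junction_role!r}")
        if len(self.exons) < 2:
            raise ModelValidationError(
                f"transcript {self.transcript_id} has {len(self.exons)} exon(s); >= 2 required"
            )
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ModelValidationError(f"{self.transcript_id}: exons on multiple sequences")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:
                raise ModelValidationError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ModelValidationError(
                f"{self.transcript_id}: exons not in 5'->3' transcript order for strand {self.strand}"
            )
        for i, e in enumerate(self.exons, start=1):
            if e.exon_index != i:
                raise ModelValidationError(f"{self.transcript_id}: exon_index sequence broken")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    def exons_genomic(self) -> tuple[Exon, ...]:
        return tuple(sorted(self.exons, key=lambda e: e.start))

    def genomic_junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor_end, acceptor_start) pairs in genomic order."""
        gx = self.exons_genomic()
        return tuple((a.end, b.start) for a, b in zip(gx, gx[1:]))

    @classmethod
    def from_intervals(
        cls,
        transcript_id: str,
        chrom: str,
        strand: str,
        intervals: Sequence[Sequence[int]],
        role: str = ALT_ROLE,
        junction_role: str | None = None,
    ) -> "TranscriptModel":
        """Build from (start, end) pairs given in transcript 5'->3' order."""
        exons = tuple(
            Exon(chrom=chrom, start=int(s), end=int(e), exon_index=i)
            for i, (s, e) in enumerate(intervals, start=1)
        )
        return cls(transcript_id, strand, exons, role, junction_role)


def junction_label(chrom: str, donor_end: int, acceptor_start: int) -> str:
    return f"{chrom}:{donor_end}-{acceptor_start}"


@dataclass(frozen=True)
class Junction:
    chrom: str
    donor_end: int
    acceptor_start: int
    label: str
    origin: frozenset[str]
    klass: str

    def __post_init__(self) -> None:
        if not self.donor_end < self.acceptor_start - 1:
            raise ModelValidationError(
                f"junction {self.label}: intron must be >= 1 bp "
                f"(donor_end {self.donor_end}, acceptor_start {self.acceptor_start})"
            )

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor_end, self.acceptor_start)


@dataclass
class JunctionCatalog:
    """All junctions of a locus plus the labels driving the fraction statistics.

    ``cterm_pair`` holds the two C-terminal distinct junction labels whose
    counts are averaged; ``cterm_main`` is the competing main-isoform junction
    between the same flanking exons.  ``utr5_distinct`` / ``utr5_main`` are the
    3-bp-shifted alternative acceptor junction and its main competitor.  Any of
    these may be ``None`` when the model does not define the corresponding
    structure; such gaps are recorded in ``warnings``.
    """

    junctions: tuple[Junction, ...]
    cterm_pair: tuple[str, str] | None = None
    cterm_main: str | None = None
    utr5_distinct: str | None = None
    utr5_main: str | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cterm_pair is not None:
            if len(self.cterm_pair) != 2:
                raise ModelValidationError("cterm_pair must contain exactly 2 labels")
            for lab in self.cterm_pair:
                if self.by_label[lab].klass != KLASS_CTERM:
                    raise ModelValidationError(f"{lab} is not a C-terminal distinct junction")
        if self.cterm_main is not None and self.by_label[self.cterm_main].klass != KLASS_MAIN:
            raise ModelValidationError("cterm_main must be a main-isoform junction")

    @property
    def by_label(self) -> dict[str, Junction]:
        return {j.label: j for j in self.junctions}

    @property
    def by_coords(self) -> dict[tuple[str, int, int], Junction]:
        return {j.coords: j for j in self.junctions}

    @property
    def chrom(self) -> str:
        return self.junctions[0].chrom

    def span(self) -> tuple[str, int, int]:
        """Genomic interval covered by all junctions (1-based inclusive)."""
        return (
            self.chrom,
            min(j.donor_end for j in self.junctions),
            max(j.acceptor_start for j in self.junctions),
        )

    def labels(self) -> tuple[str, ...]:
        return tuple(j.label for j in self.junctions)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [j.label for j in self.junctions],
                "chrom": [j.chrom for j in self.junctions],
                "donor_end": [j.donor_end for j in self.junctions],
                "acceptor_start": [j.acceptor_start for j in self.junctions],
                "klass": [j.klass for j in self.junctions],
                "origin": [";".join(sorted(j.origin)) for j in self.junctions],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def derive_junctions(
    transcripts: Sequence[TranscriptModel],
    roles: Mapping[str, str] | None = None,
) -> JunctionCatalog:
    """Derive the junction catalog from a set of transcript models.

    ``roles`` maps transcript accessions to one of :data:`JUNCTION_ROLES`;
    when omitted, the per-transcript ``junction_role`` attributes are used.
    Exactly one transcript must carry ``role == "main"``.  The result is
    independent of transcript input order.
    """
    mains = [t for t in transcripts if t.role == MAIN_ROLE]
    if len(mains) != 1:
        raise ModelValidationError(
            f"expected exactly one main transcript, found {len(mains)}"
        )
    main = mains[0]
    known = {t.transcript_id for t in transcripts}
    if roles is None:
        roles = {
            t.transcript_id: t.junction_role
            for t in transcripts
            if t.junction_role is not None
        }
    unknown = set(roles) - known
    if unknown:
        raise ModelValidationError(f"roles reference unknown transcripts: {sorted(unknown)}")
    for tid, r in roles.items():
        if r not in JUNCTION_ROLES:
            raise ModelValidationError(f"unknown junction role {r!r} for {tid}")

    chroms = {t.chrom for t in transcripts}
    if len(chroms) != 1:
        raise ModelValidationError("all transcripts must share one sequence (single locus)")
    chrom = chroms.pop()

    origin: dict[tuple[int, int], set[str]] = {}
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        for j in t.genomic_junctions():
            origin.setdefault(j, set()).add(t.transcript_id)
    main_set = set(main.genomic_junctions())

    cterm_ids = {tid for tid, r in roles.items() if r == "cterm"}
    gamma_ids = {tid for tid, r in roles.items() if r == "gamma"}
    utr5_ids = {tid for tid, r in roles.items() if r == "utr5"}

    warnings: list[str] = []

    # C-terminal pair: non-main junctions shared by every cterm transcript.
    cterm_coords: list[tuple[int, int]] = []
    if cterm_ids:
        cterm_coords = sorted(
            j
            for j, org in origin.items()
            if j not in main_set and cterm_ids <= org
        )
        if len(cterm_coords) == 0:
            warnings.append("cterm transcripts define no junctions distinct from main")
        elif len(cterm_coords) != 2:
            raise ModelValidationError(
                f"expected 2 shared C-terminal distinct junctions, found {len(cterm_coords)}"
            )
    else:
        warnings.append("no transcript has the 'cterm' role; cterm_pair unset")

    # Main competitor: shares the donor of one pair member and the acceptor of
    # the other (it splices the outer exons directly, skipping the extra exon).
    cterm_main_coords: tuple[int, int] | None = None
    if len(cterm_coords) == 2:
        donors = {c[0] for c in cterm_coords}
        acceptors = {c[1] for c in cterm_coords}
        hits = [m for m in main_set if m[0] in donors and m[1] in acceptors]
        if len(hits) == 1:
            cterm_main_coords = hits[0]
        else:
            warnings.append("no unique main junction competes with the C-terminal pair")

    # 5'UTR alternative acceptor: a non-main junction of the utr5 transcript
    # differing from a main junction by exactly 3 bases on one boundary.  On
    # the plus strand the shift lands on acceptor_start; on the minus strand
    # (the TP53 situation) the transcript's acceptor is the genomic donor_end.
    utr5_coords: tuple[int, int] | None = None
    utr5_main_coords: tuple[int, int] | None = None
    if utr5_ids:
        candidates = []
        for j, org in origin.items():
            if j in main_set or not (org & utr5_ids):
                continue
            for m in main_set:
                if (j[0] == m[0] and abs(j[1] - m[1]) == 3) or (
                    j[1] == m[1] and abs(j[0] - m[0]) == 3
                ):
                    candidates.append((j, m))
        if len(candidates) == 1:
            utr5_coords, utr5_main_coords = candidates[0]
        else:
            warnings.append(
                f"could not identify a unique 3-bp-shifted 5'UTR junction "
                f"({len(candidates)} candidates)"
            )
    else:
        warnings.append("no transcript has the 'utr5' role; utr5_distinct unset")

    def classify(coords: tuple[int, int], org: set[str]) -> str:
        if coords in main_set:
            return KLASS_MAIN
        if coords in cterm_coords:
            return KLASS_CTERM
        if coords == utr5_coords:
            return KLASS_UTR5
        if gamma_ids and org <= gamma_ids:
            return KLASS_GAMMA
        return KLASS_OTHER

    junctions = tuple(
        Junction(
            chrom=chrom,
            donor_end=d,
            acceptor_start=a,
            label=junction_label(chrom, d, a),
            origin=frozenset(origin[(d, a)]),
            klass=classify((d, a), origin[(d, a)]),
        )
        for d, a in sorted(origin)
    )

    lab = lambda c: junction_label(chrom, *c) if c is not None else None
    return JunctionCatalog(
        junctions=junctions,
        cterm_pair=tuple(lab(c) for c in cterm_coords) if len(cterm_coords) == 2 else None,
        cterm_main=lab(cterm_main_coords),
        utr5_distinct=lab(utr5_coords),
        utr5_main=lab(utr5_main_coords),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# serialization


def _transcripts_from_dict(doc: dict) -> list[TranscriptModel]:
    try:
        chrom = doc["chrom"]
        entries = doc["transcripts"]
    except KeyError as exc:
        raise InputDataError(f"gene-model JSON missing key {exc}") from None
    out = []
    for entry in entries:
        try:
            out.append(
                TranscriptModel.from_intervals(
                    transcript_id=entry["id"],
                    chrom=chrom,
                    strand=entry["strand"],
                    intervals=entry["exons"],
                    role=entry.get("role", ALT_ROLE),
                    junction_role=entry.get("junction_role"),
                )
            )
        except KeyError as exc:
            raise InputDataError(f"transcript entry missing key {exc}") from None
    return out


def _load_json_model(path: Path) -> list[TranscriptModel]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputDataError(f"{path}: JSON parse error at line {exc.lineno}") from exc
    return _transcripts_from_dict(doc)


def _load_gff3_model(path: Path) -> list[TranscriptModel]:
    import gffutils

    # cheap structural pre-check so parse errors name the offending line
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise InputDataError(f"{path}: malformed GFF3 at line {lineno}")

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    parent_meta: dict[str, dict] = {}
    order: list[str] = []
    exons: dict[str, list] = {}
    for feat in db.all_features(order_by=None):
        if feat.featuretype in ("mRNA", "transcript"):
            tid = feat.id
            parent_meta[tid] = {
                "strand": feat.strand,
                "role": feat.attributes.get("role", [ALT_ROLE])[0],
                "junction_role": (feat.attributes.get("junction_role") or [None])[0],
            }
            if tid not in order:
                order.append(tid)
        elif feat.featuretype == "exon":
            parents = feat.attributes.get("Parent")
            if not parents:
                raise InputDataError(f"{path}: exon feature without Parent attribute")
            for tid in parents:
                if tid not in order:
                    order.append(tid)
                exons.setdefault(tid, []).append(feat)

    out = []
    for tid in order:
        feats = exons.get(tid, [])
        if len(feats) < 2:
            raise ModelValidationError(f"{path}: transcript {tid} has < 2 exons")
        meta = parent_meta.get(tid, {})
        strand = meta.get("strand") or feats[0].strand
        feats.sort(key=lambda f: f.start)
        if strand == "-":
            feats = feats[::-1]
        intervals = [(f.start, f.end) for f in feats]
        out.append(
            TranscriptModel.from_intervals(
                transcript_id=tid,
                chrom=feats[0].seqid,
                strand=strand,
                intervals=intervals,
                role=meta.get("role", ALT_ROLE),
                junction_role=meta.get("junction_role"),
            )
        )
    return out


def load_gene_model(path: str | Path, dialect: str | None = None) -> list[TranscriptModel]:
    """Load transcript models from JSON or GFF3 (1-based inclusive coordinates).

    ``dialect`` is inferred from the extension when not given.  Transcripts are
    returned in file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"gene-model file not found: {path}")
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "json"
    if dialect == "json":
        return _load_json_model(path)
    if dialect == "gff3":
        return _load_gff3_model(path)
    raise ConfigurationError(f"unknown gene-model dialect {dialect!r}")


def write_gene_model(
    transcripts: Sequence[TranscriptModel], path: str | Path, dialect: str | None = None
) -> None:
    """Write transcript models as JSON or GFF3 (round-trips with load_gene_model)."""
    path = Path(path)
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "json"
    if dialect == "json":
        doc = {
            "chrom": transcripts[0].chrom,
            "transcripts": [
                {
                    "id": t.transcript_id,
                    "strand": t.strand,
                    "role": t.role,
                    **({"junction_role": t.junction_role} if t.junction_role else {}),
                    "exons": [[e.start, e.end] for e in t.exons],
                }
                for t in transcripts
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    if dialect == "gff3":
        lines = ["##gff-version 3"]
        for t in transcripts:
            gx = t.exons_genomic()
            attrs = f"ID={t.transcript_id};role={t.role}"
            if t.junction_role:
                attrs += f";junction_role={t.junction_role}"
            lines.append(
                "\t".join(
                    [t.chrom, "tp53junc", "mRNA", str(gx[0].start), str(gx[-1].end),
                     ".", t.strand, ".", attrs]
                )
            )
            for e in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "tp53junc", "exon", str(e.start), str(e.end),
                         ".", t.strand, ".", f"Parent={t.transcript_id}"]
                    )
                )
        path.write_text("\n".join(lines) + "\n")
        return
    raise ConfigurationError(f"unknown gene-model dialect {dialect!r}")


@lru_cache(maxsize=1)
def _builtin_model_doc() -> str:
    return (resources.files(__package__) / "data" / "tp53_model.json").read_text()


def builtin_tp53_model() -> list[TranscriptModel]:
    """The bundled TP53 (chr17, minus strand) model: NM_000546.6 plus the nine
    alternative isoforms with junctions distinct from the main isoform.

    Coordinates mirror the public reference annotation (GRCh38) for the listed
    accessions and live in a packaged data file so the annotation can be
    swapped without touching code.
    """
    return _transcripts_from_dict(json.loads(_builtin_model_doc()))


def builtin_tp53_catalog() -> JunctionCatalog:
    """Junction catalog derived from :func:`builtin_tp53_model`."""
    return derive_junctions(builtin_tp53_model())
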