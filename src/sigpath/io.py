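"""Readers and writers for the tabular formats the pipeline consumes.

Supported formats
-----------------
- GO annotations: GAF 2.x or a two-column TSV (``accession<TAB>GO-id`` with an
  optional third aspect column).
- Pathway membership: TSV with ``pathway<TAB>accession`` rows.
- Protein-protein interactions: TSV with two accession columns per row,
  treated as undirected edges.
- Homology hits: BLAST/PSI-BLAST tabular output (outfmt 6), 12 columns with
  the E-value in column 11.

All writers emit UTF-8 TSV with a single ``#``-prefixed header line.
Accessions are compared case-sensitively after whitespace stripping; pairs of
interacting proteins are canonicalized to lexicographic order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d+$")

#: GAF aspect code -> ontology aspect name
ASPECT_NAMES = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
_ASPECT_SET = frozenset(ASPECT_NAMES.values())


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_go_id(term: str, path: Path, lineno: int) -> str:
    if not GO_ID_PATTERN.match(term):
        raise ParseError(f"{path}:{lineno}: malformed GO identifier {term!r}")
    return term


def _check_accession(acc: str, path: Path, lineno: int) -> str:
    acc = acc.strip()
    if not acc:
        raise ParseError(f"{path}:{lineno}: empty accession")
    return acc


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered protein pair ``{a, b}`` in lexicographic order."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class AnnotationMap:
    """Protein accession -> set of GO term identifiers.

    ``aspect`` optionally maps each GO term to its ontology aspect
    (biological_process / molecular_function / cellular_component); it is
    populated when reading GAF or a three-column TSV.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    aspect: dict[str, str] | None = None

    def add(self, accession: str, term: str) -> None:
        self.entries.setdefault(accession, set()).add(term)

    def terms_of(self, accession: str) -> set[str]:
        """Annotation set of a protein; empty set when unannotated."""
        return self.entries.get(accession, set())

    def merged(self, other: "AnnotationMap") -> "AnnotationMap":
        """Union of two annotation maps (entries and aspect tables)."""
        out = AnnotationMap()
        for src in (self, other):
            for acc, terms in src.entries.items():
                out.entries.setdefault(acc, set()).update(terms)
            if src.aspect:
                out.aspect = dict(out.aspect or {})
                out.aspect.update(src.aspect)
        return out

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PathwayMembership:
    """Pathway name -> member accessions, with an integer label per pathway.

    ``label_index`` is a bijection from pathway names onto ``1..d`` assigned
    in sorted pathway-name order, so label numbering is reproducible across
    runs regardless of file row order.
    """

    pathways: dict[str, set[str]] = field(default_factory=dict)
    label_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_pathways(cls, pathways: Mapping[str, Iterable[str]]) -> "PathwayMembership":
        paths = {name: set(members) for name, members in pathways.items()}
        index = {name: i + 1 for i, name in enumerate(sorted(paths))}
        return cls(pathways=paths, label_index=index)

    @property
    def d(self) -> int:
        return len(self.pathways)

    @property
    def member_universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return out

    def name_of_label(self, label: int) -> str:
        for name, idx in self.label_index.items():
            if idx == label:
                return name
        raise KeyError(label)


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network.

    Edges are stored once, in canonical (lexicographic) order; self
    interactions are dropped on ingestion and counted in
    ``n_self_dropped``.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    n_self_dropped: int = 0

    @property
    def node_set(self) -> set[str]:
        nodes: set[str] = set()
        for a, b in self.edges:
            nodes.add(a)
            nodes.add(b)
        return nodes

    def add_edge(self, a: str, b: str, *, keep_self: bool = False) -> None:
        if a == b and not keep_self:
            self.n_self_dropped += 1
            return
        self.edges.add(canonical_pair(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class HomologMap:
    """Query accession -> set of homologous subject accessions.

    Only hits at or below ``evalue_cutoff`` are retained; self-hits are
    always removed.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    evalue_cutoff: float = 10.0

    def homologs_of(self, accession: str) -> set[str]:
        return self.entries.get(accession, set())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path, format: str = "tsv") -> AnnotationMap:
    """Read GO annotations from a GAF 2.x or two/three-column TSV file.

    Duplicate (protein, term) rows collapse by construction. GAF rows whose
    qualifier contains ``NOT`` are skipped (standard negation semantics).

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` or ``"gaf"``.
    """
    path = Path(path)
    if format not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {format!r}")
    amap = AnnotationMap()
    n_rows = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            cols = line.split("\t")
            if format == "gaf":
                if len(cols) < 9:
                    raise ParseError(f"{path}:{lineno}: GAF row has {len(cols)} columns, expected >= 9")
                qualifier = cols[3]
                if "NOT" in qualifier.split("|"):
                    continue
                acc = _check_accession(cols[1], path, lineno)
                term = _check_go_id(cols[4].strip(), path, lineno)
                aspect_code = cols[8].strip()
                if aspect_code in ASPECT_NAMES:
                    if amap.aspect is None:
                        amap.aspect = {}
                    amap.aspect[term] = ASPECT_NAMES[aspect_code]
            else:
                if len(cols) < 2:
                    raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}")
                acc = _check_accession(cols[0], path, lineno)
                term = _check_go_id(cols[1].strip(), path, lineno)
                if len(cols) >= 3 and cols[2].strip():
                    aspect = cols[2].strip()
                    if aspect not in _ASPECT_SET:
                        raise ParseError(f"{path}:{lineno}: unknown GO aspect {aspect!r}")
                    if amap.aspect is None:
                        amap.aspect = {}
                    amap.aspect[term] = aspect
            amap.add(acc, term)
            n_rows += 1
    if n_rows == 0:
        logger.warning("no annotation rows read from %s", path)
    return amap


def write_annotations(amap: AnnotationMap, path: str | Path) -> None:
    """Write an AnnotationMap as TSV (accession, GO id[, aspect])."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# accession\tgo_id\taspect\n")
        for acc in sorted(amap.entries):
            for term in sorted(amap.entries[acc]):
                aspect = (amap.aspect or {}).get(term, "")
                fh.write(f"{acc}\t{term}\t{aspect}\n")


def read_pathway_membership(
    path: str | Path,
    merge_groups: Mapping[str, Iterable[str]] | None = None,
) -> PathwayMembership:
    """Read a ``pathway<TAB>accession`` membership table.

    ``merge_groups`` unions several pathways under one group name, e.g. the
    eleven interleukin sub-pathways collapsed into a single ``IL`` class.
    Label indices are assigned in sorted pathway-name order after merging.
    """
    path = Path(path)
    raw: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            pathway = cols[0].strip()
            acc = _check_accession(cols[1], path, lineno)
            if not pathway:
                raise ParseError(f"{path}:{lineno}: empty pathway name")
            raw.setdefault(pathway, set()).add(acc)
    if merge_groups:
        merged: dict[str, set[str]] = {}
        consumed: set[str] = set()
        for group, names in merge_groups.items():
            members: set[str] = set()
            for name in names:
                if name not in raw:
                    raise ValueError(f"merge group {group!r} references unknown pathway {name!r}")
                members |= raw[name]
                consumed.add(name)
            merged[group] = members
        for name, members in raw.items():
            if name not in consumed:
                merged[name] = members
        raw = merged
    return PathwayMembership.from_pathways(raw)


def write_pathway_membership(membership: PathwayMembership, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# pathway\taccession\n")
        for name in sorted(membership.pathways):
            for acc in sorted(membership.pathways[name]):
                fh.write(f"{name}\t{acc}\n")


def read_ppi_edges(path: str | Path, *, keep_self: bool = False) -> PPINetwork:
    """Read a two-column undirected PPI edge list.

    Duplicate rows and reversed duplicates collapse to one edge; self
    interactions are dropped (and counted) unless ``keep_self`` is set.
    """
    path = Path(path)
    net = PPINetwork()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}")
            a = _check_accession(cols[0], path, lineno)
            b = _check_accession(cols[1], path, lineno)
            net.add_edge(a, b, keep_self=keep_self)
    if net.n_self_dropped:
        logger.info("dropped %d self-interactions from %s", net.n_self_dropped, path)
    return net


def write_ppi_edges(network: PPINetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def read_blast_tabular(path: str | Path, evalue_cutoff: float = 10.0) -> HomologMap:
    """Read BLAST/PSI-BLAST tabular hits (outfmt 6) into a HomologMap.

    Keeps hits with E-value <= ``evalue_cutoff`` (default 10, the permissive
    threshold used for homolog harvesting) and removes query==subject
    self-hits.
    """
    path = Path(path)
    hmap = HomologMap(evalue_cutoff=evalue_cutoff)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            query = _check_accession(cols[0], path, lineno)
            subject = _check_accession(cols[1], path, lineno)
            try:
                evalue = float(cols[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric E-value {cols[10]!r}") from exc
            if evalue > evalue_cutoff or query == subject:
                continue
            hmap.entries.setdefault(query, set()).add(subject)
    return hmap


def write_blast_tabular(hmap: HomologMap, path: str | Path, evalue: float = 1e-5) -> None:
    """Write a HomologMap as minimal 12-column BLAST tabular rows.

    Alignment coordinates carry placeholder values; only the query, subject
    and E-value columns are meaningful on read-back.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend\tsstart\tsend\tevalue\tbitscore\n")
        for query in sorted(hmap.entries):
            for subject in sorted(hmap.entries[query]):
                fh.write(
                    f"{query}\t{subject}\t100.0\t100\t0\t0\t1\t100\t1\t100\t{evalue:g}\t200.0\n"
                )
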