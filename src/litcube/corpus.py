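"""Corpus construction: article XML parsing, deduplication, and MeSH-tree
domain assignment.

A *cell* is one domain-specific subset of the document corpus (one
cardiovascular disease, comorbidity, or pathological mechanism).  A document
belongs to the cell of domain ``d`` iff one of its MeSH descriptors sits at
or below one of ``d``'s root descriptors in the MeSH tree; descent is tested
on dotted tree numbers at dot boundaries, so ``C14.280`` covers
``C14.280.434`` but not ``C14.2801``.  Documents may carry descriptors under
several domain roots and then belong to every matching cell (multi-label).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]+)*$")


@dataclass
class Document:
    """One article record: identifiers, text fields, MeSH annotations.

    ``pmid`` must be non-empty; text fields may be empty strings but are
    never None.  ``date`` is parsed leniently (year-only allowed) and is
    carried for provenance only — scoring ignores it.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    keywords: list[str] = field(default_factory=list)
    mesh_ids: list[str] = field(default_factory=list)
    date: _date | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("Document requires a non-empty pmid")

    @property
    def text(self) -> str:
        """Concatenated searchable text: title, abstract, keywords."""
        return " ".join([self.title, self.abstract, *self.keywords])


@dataclass
class MeshTree:
    """MeSH descriptor table: id -> display name and set of tree numbers."""

    names: dict[str, str]
    tree_numbers: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for did, numbers in self.tree_numbers.items():
            for tn in numbers:
                if not _TREE_NUMBER_RE.match(tn):
                    raise ValueError(
                        f"descriptor {did}: malformed tree number {tn!r}"
                    )

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.tree_numbers


@dataclass(frozen=True)
class DomainSpec:
    """A named domain and the MeSH descriptor ids rooting its subtree."""

    name: str
    roots: frozenset[str]

    def __post_init__(self) -> None:
        if not self.roots:
            raise ValueError(f"domain {self.name!r} has no root descriptors")


@dataclass
class Cell:
    """One domain's document subset; a pmid may appear in several cells."""

    domain: str
    doc_ids: set[str]

    def __len__(self) -> int:
        return len(self.doc_ids)


# ---------------------------------------------------------------------------
# readers


def _parse_date(node: etree._Element | None) -> _date | None:
    if node is None:
        return None
    year = node.findtext("Year")
    if not year or not year.isdigit():
        return None
    month = node.findtext("Month") or "1"
    day = node.findtext("Day") or "1"
    months = {
        "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
        "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
    }
    if not month.isdigit():
        month = str(months.get(month[:3].lower(), 1))
    try:
        return _date(int(year), int(month), int(day) if day.isdigit() else 1)
    except ValueError:
        return _date(int(year), 1, 1)


def read_medline_xml(source: str | IO[bytes]) -> list[Document]:
    """Parse a PubmedArticleSet XML stream into Documents.

    One Document per ``PubmedArticle``; missing abstracts or keyword lists
    yield empty fields.  MeSH headings are captured by descriptor UI.
    Articles lacking a PMID are skipped with a warning.  Malformed XML
    raises :class:`lxml.etree.XMLSyntaxError` (which names the position).
    """
    tree = etree.parse(source)
    docs: list[Document] = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid or not pmid.strip():
            logger.warning("skipping article without PMID")
            continue
        title = (art.findtext(".//ArticleTitle") or "").strip()
        abstract = " ".join(
            (t.text or "").strip()
            for t in art.findall(".//Abstract/AbstractText")
        ).strip()
        keywords = [
            (k.text or "").strip()
            for k in art.findall(".//KeywordList/Keyword")
            if (k.text or "").strip()
        ]
        mesh_ids = [
            d.get("UI", "").strip()
            for d in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if d.get("UI", "").strip()
        ]
        pub_date = _parse_date(art.find(".//PubDate"))
        docs.append(
            Document(
                pmid=pmid.strip(),
                title=title,
                abstract=abstract,
                keywords=keywords,
                mesh_ids=mesh_ids,
                date=pub_date,
            )
        )
    return docs


def read_mesh_table(path: str | IO[str]) -> MeshTree:
    """Read a MeSH descriptor TSV: descriptor_id, name, tree_numbers.

    ``tree_numbers`` is semicolon-separated; a descriptor may own several.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"descriptor_id", "name", "tree_numbers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MeSH table missing columns: {sorted(missing)}")
    names: dict[str, str] = {}
    numbers: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        did = row.descriptor_id.strip()
        names[did] = row.name.strip()
        numbers[did] = frozenset(
            t.strip() for t in row.tree_numbers.split(";") if t.strip()
        )
    return MeshTree(names=names, tree_numbers=numbers)


def read_domain_config(path: str | IO[str]) -> list[DomainSpec]:
    """Read a YAML mapping of domain name -> list of root descriptor ids."""
    import yaml

    if hasattr(path, "read"):
        raw = yaml.safe_load(path)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not raw:
        raise ValueError("domain config must be a non-empty mapping")
    specs = [
        DomainSpec(name=str(name), roots=frozenset(map(str, roots)))
        for name, roots in raw.items()
    ]
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("duplicate domain names in config")
    return specs


# ---------------------------------------------------------------------------
# operations


def deduplicate(docs: Iterable[Document]) -> list[Document]:
    """Keep the first record per pmid, preserving input order.

    Duplicate count is logged.  Idempotent.
    """
    seen: set[str] = set()
    out: list[Document] = []
    dropped = 0
    for d in docs:
        if d.pmid in seen:
            dropped += 1
            continue
        seen.add(d.pmid)
        out.append(d)
    if dropped:
        logger.info("deduplicate: removed %d duplicate record(s)", dropped)
    return out


def _is_descendant(tree_number: str, root_number: str) -> bool:
    """True iff tree_number equals root_number or extends it at a dot."""
    if tree_number == root_number:
        return True
    return tree_number.startswith(root_number + ".")


def assign_domains(
    docs: Iterable[Document],
    tree: MeshTree,
    specs: Iterable[DomainSpec],
) -> list[Cell]:
    """Assign documents to domain cells by MeSH descriptor-tree descent.

    A document joins the cell of domain ``d`` iff some tree number of some
    of its MeSH descriptors equals, or extends at a dot boundary, some tree
    number of some root descriptor of ``d``.  Only MeSH descriptors are
    consulted — never keywords or free text.  Documents without MeSH
    descriptors belong to no cell but remain in the corpus.
    """
    specs = list(specs)
    for spec in specs:
        absent = [r for r in spec.roots if r not in tree]
        if absent:
            raise KeyError(
                f"domain {spec.name!r}: root descriptor(s) absent from MeSH "
                f"tree: {sorted(absent)}"
            )
    root_numbers = {
        spec.name: frozenset(
            tn for r in spec.roots for tn in tree.tree_numbers[r]
        )
        for spec in specs
    }
    cells = {spec.name: Cell(domain=spec.name, doc_ids=set()) for spec in specs}
    for doc in docs:
        doc_numbers = [
            tn
            for did in doc.mesh_ids
            if did in tree
            for tn in tree.tree_numbers[did]
        ]
        if not doc_numbers:
            continue
        for name, roots in root_numbers.items():
            if any(
                _is_descendant(tn, root) for tn in doc_numbers for root in roots
            ):
                cells[name].doc_ids.add(doc.pmid)
    return [cells[spec.name] for spec in specs]


def shared_document_matrix(cells: list[Cell]) -> pd.DataFrame:
    """Pairwise shared-abstract counts: diagonal |cell|, off-diag |c_i ∩ c_j|."""
    if not cells:
        raise ValueError("shared_document_matrix requires at least one cell")
    names = [c.domain for c in cells]
    n = len(cells)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            shared = len(cells[i].doc_ids & cells[j].doc_ids)
            mat[i, j] = mat[j, i] = shared
    return pd.DataFrame(mat, index=names, columns=names)
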