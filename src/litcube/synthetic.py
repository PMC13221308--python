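"""Synthetic corpora, expression tables and tissue tables with planted
ground truth.

The corpus generator emulates the structure of a MeSH-partitioned abstract
collection: each domain cell has its own root descriptor, every document
receives a child descriptor under its cell's root (so domain assignment
exercises real tree descent), and protein mentions are drawn per document
from a closed synthetic vocabulary — each protein owns a unique single-token
synonym, which keeps brute-force oracle counting trivial.  Background
proteins appear in every cell with per-protein rates drawn log-uniformly
(mimicking the heavy right tail of real protein mention frequencies);
planted cell-exclusive proteins appear only in their home cell at a
configurable multiple of the mean background rate; shared proteins appear
in a designated subset of cells.

The expression generator emulates a case/control biopsy proteomics table:
Gaussian noise around per-protein baselines, with a planted subset shifted
by delta times the noise standard deviation in the case group.  Defaults
mirror a small clinical cohort (9 controls, 10 cases, 2,180 proteins).

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from litcube.corpus import Cell, Document, DomainSpec, MeshTree
from litcube.lexicon import Lexicon, ProteinEntry
from litcube.validate import ExpressionTable


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for a synthetic literature corpus."""

    n_cells: int = 6
    docs_per_cell: int = 200
    n_background_proteins: int = 100
    planted_per_cell: int = 20
    planted_multiplier: float = 10.0
    n_shared_proteins: int = 0
    shared_member_cells: int = 2
    mentions_per_doc_mean: float = 8.0
    multilabel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.docs_per_cell < 1:
            raise ValueError("need >= 1 cell and >= 1 document per cell")
        if self.planted_multiplier < 1:
            raise ValueError("planted multiplier must be >= 1")
        if min(
            self.n_background_proteins,
            self.planted_per_cell,
            self.n_shared_proteins,
        ) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Study conditions for a synthetic case/control expression table."""

    n_proteins: int = 2180
    n_case: int = 10
    n_control: int = 9
    n_planted: int = 20
    delta: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_proteins:
            raise ValueError("planted count exceeds protein count")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure echoed back alongside generated data."""

    planted_by_cell: dict[str, list[str]] = field(default_factory=dict)
    shared_proteins: dict[str, list[str]] = field(default_factory=dict)
    background_proteins: list[str] = field(default_factory=list)
    planted_differential: list[str] = field(default_factory=list)
    dominant_tissue: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticCorpus:
    """Everything one pipeline run needs, with ground truth attached."""

    documents: list[Document]
    mesh_tree: MeshTree
    domain_specs: list[DomainSpec]
    cells: list[Cell]
    lexicon: Lexicon
    truth: GroundTruth


def _protein_entry(uid: str, idx: int) -> ProteinEntry:
    # unique single-token synonym per protein: closed vocabulary
    return ProteinEntry(
        uniprot_id=uid,
        gene_symbol=f"GS{idx}",
        synonyms=(f"prot{idx}tok",),
    )


def generate_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Generate documents, MeSH scaffolding, lexicon and ground truth.

    Cell names are CELL0..CELL{n-1}; cell i's root descriptor D{i:04d}ROOT
    owns tree number C{i+1:02d}, and each document carries a child
    descriptor with tree number C{i+1:02d}.100 so membership is decided by
    dotted-prefix descent.  A ``multilabel_fraction`` of documents also
    carries the next cell's child descriptor.
    """
    rng = np.random.default_rng(spec.seed)
    cell_names = [f"CELL{i}" for i in range(spec.n_cells)]

    # --- MeSH scaffolding: per cell a root and a child descriptor
    names, numbers = {}, {}
    root_ids, child_ids = [], []
    for i, cn in enumerate(cell_names):
        rid, cid = f"D{i:04d}R", f"D{i:04d}C"
        names[rid] = f"{cn} root"
        names[cid] = f"{cn} child"
        numbers[rid] = frozenset({f"C{i + 1:02d}"})
        numbers[cid] = frozenset({f"C{i + 1:02d}.100"})
        root_ids.append(rid)
        child_ids.append(cid)
    tree = MeshTree(names=names, tree_numbers=numbers)
    specs = [
        DomainSpec(name=cn, roots=frozenset({root_ids[i]}))
        for i, cn in enumerate(cell_names)
    ]

    # --- protein universe
    idx = 0
    entries: list[ProteinEntry] = []
    background: list[str] = []
    for _ in range(spec.n_background_proteins):
        uid = f"P{idx:05d}"
        entries.append(_protein_entry(uid, idx))
        background.append(uid)
        idx += 1
    planted_by_cell: dict[str, list[str]] = {}
    for cn in cell_names:
        ids = []
        for _ in range(spec.planted_per_cell):
            uid = f"P{idx:05d}"
            entries.append(_protein_entry(uid, idx))
            ids.append(uid)
            idx += 1
        planted_by_cell[cn] = ids
    shared: dict[str, list[str]] = {}
    for s in range(spec.n_shared_proteins):
        uid = f"P{idx:05d}"
        entries.append(_protein_entry(uid, idx))
        members = [
            cell_names[(s + j) % spec.n_cells]
            for j in range(min(spec.shared_member_cells, spec.n_cells))
        ]
        shared[uid] = members
        idx += 1
    lexicon = Lexicon(entries)
    token_of = {e.uniprot_id: e.synonyms[0] for e in entries}

    # --- mention rates: log-uniform background, multiplier x mean for planted
    bg_rates = (
        10 ** rng.uniform(-1, 0, size=len(background))
        if background
        else np.array([])
    )
    mean_bg = float(bg_rates.mean()) if bg_rates.size else 1.0
    planted_rate = spec.planted_multiplier * mean_bg

    documents: list[Document] = []
    pmid = 0
    for i, cn in enumerate(cell_names):
        cell_shared = [u for u, m in shared.items() if cn in m]
        pool = (
            background + planted_by_cell[cn] + cell_shared
        )
        weights = np.concatenate(
            [
                bg_rates,
                np.full(len(planted_by_cell[cn]), planted_rate),
                np.full(len(cell_shared), mean_bg),
            ]
        )
        probs = weights / weights.sum() if weights.sum() > 0 else None
        for _ in range(spec.docs_per_cell):
            pmid += 1
            mesh = [child_ids[i]]
            if spec.multilabel_fraction > 0 and rng.random() < spec.multilabel_fraction:
                mesh.append(child_ids[(i + 1) % spec.n_cells])
            n_mentions = rng.poisson(spec.mentions_per_doc_mean)
            tokens: list[str] = []
            if probs is not None and n_mentions > 0:
                picks = rng.choice(len(pool), size=n_mentions, p=probs)
                tokens = [token_of[pool[j]] for j in picks]
            filler = ["filler"] * int(rng.integers(3, 8))
            body = tokens + filler
            rng.shuffle(body)
            documents.append(
                Document(
                    pmid=str(pmid),
                    title=f"synthetic abstract {pmid}",
                    abstract=" ".join(body),
                    keywords=[],
                    mesh_ids=mesh,
                )
            )

    from litcube.corpus import assign_domains

    cells = assign_domains(documents, tree, specs)
    truth = GroundTruth(
        planted_by_cell=planted_by_cell,
        shared_proteins=shared,
        background_proteins=background,
        params={"corpus_spec": spec},
    )
    return SyntheticCorpus(
        documents=documents,
        mesh_tree=tree,
        domain_specs=specs,
        cells=cells,
        lexicon=lexicon,
        truth=truth,
    )


def generate_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[ExpressionTable, GroundTruth]:
    """Case/control expression matrix with a planted group mean shift.

    Per-protein baselines are uniform on [8, 12] (arbitrary abundance
    units); every value gets Gaussian noise of sd ``noise_sd``; the first
    ``n_planted`` proteins gain ``delta * noise_sd`` in the case group.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:05d}" for i in range(spec.n_proteins)]
    samples = [f"ctrl{i}" for i in range(spec.n_control)] + [
        f"case{i}" for i in range(spec.n_case)
    ]
    groups = pd.Series(
        ["control"] * spec.n_control + ["case"] * spec.n_case,
        index=samples,
        name="group",
    )
    baselines = rng.uniform(8, 12, size=spec.n_proteins)
    n_samples = spec.n_control + spec.n_case
    values = baselines[None, :] + rng.normal(
        0, spec.noise_sd, size=(n_samples, spec.n_proteins)
    )
    planted = proteins[: spec.n_planted]
    case_rows = np.arange(spec.n_control, n_samples)
    values[np.ix_(case_rows, np.arange(spec.n_planted))] += (
        spec.delta * spec.noise_sd
    )
    table = ExpressionTable(
        values=pd.DataFrame(values, index=samples, columns=proteins),
        groups=groups,
    )
    truth = GroundTruth(
        planted_differential=planted,
        params={"expression_spec": spec},
    )
    return table, truth


def generate_tissue_table(
    n_proteins: int,
    tissues: list[str],
    seed: int = 0,
    dominant_factor: float = 5.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """HPA-style long table where each protein has one known dominant tissue.

    Background expression is uniform on [1, 10] per tissue; the dominant
    tissue's value is the protein's background maximum times
    ``dominant_factor``, so argmax assignment recovers the truth exactly.
    """
    if not tissues:
        raise ValueError("at least one tissue required")
    rng = np.random.default_rng(seed)
    rows = []
    dominant: dict[str, str] = {}
    for i in range(n_proteins):
        uid = f"P{i:05d}"
        values = rng.uniform(1, 10, size=len(tissues))
        dom = tissues[int(rng.integers(len(tissues)))]
        dominant[uid] = dom
        vmax = values.max()
        for t, v in zip(tissues, values):
            rows.append((uid, t, float(dominant_factor * vmax if t == dom else v)))
    table = pd.DataFrame(rows, columns=["protein_id", "tissue", "value"])
    truth = GroundTruth(
        dominant_tissue=dominant,
        params={"n_proteins": n_proteins, "tissues": tissues, "seed": seed},
    )
    return table, truth


def stress_corpus(seed: int = 1) -> SyntheticCorpus:
    """Six-cell stress benchmark: ~2,000 documents and 500 proteins.

    Five cells behave like ordinary literature cells; the last cell's
    documents are rewritten so that a single designated protein accounts
    for ALL phrase occurrences there.  That protein appears nowhere else,
    so its popularity and distinctiveness both reach 1.0 exactly — the
    composite score's upper bound is attained, which makes this corpus a
    sharp probe of the score-bound invariant.  The dominant accession is
    recorded in ``truth.params["dominant_protein"]``.
    """
    spec = SyntheticCorpusSpec(
        n_cells=6,
        docs_per_cell=333,
        n_background_proteins=380,
        planted_per_cell=20,
        planted_multiplier=10.0,
        seed=seed,
    )
    corpus = generate_corpus(spec)
    rng = np.random.default_rng(seed + 1)
    last = corpus.domain_specs[-1].name
    dominant = corpus.truth.planted_by_cell[last][0]
    token = {
        e.uniprot_id: e.synonyms[0] for e in corpus.lexicon.entries
    }[dominant]
    last_docs = {c.domain: c.doc_ids for c in corpus.cells}[last]
    for d in corpus.documents:
        if d.pmid in last_docs:
            reps = int(rng.integers(1, 6))
            d.abstract = " ".join([token] * reps + ["filler"])
    corpus.truth.params["dominant_protein"] = dominant
    corpus.truth.params["dominant_cell"] = last
    return corpus


# ---------------------------------------------------------------------------
# file emission: the exact formats the real pipeline consumes


def write_corpus_files(corpus: SyntheticCorpus, outdir: str) -> dict[str, str]:
    """Write articles XML, MeSH TSV, domain YAML and dictionary TSV.

    Returns a mapping of logical name -> path; files round-trip through
    the pipeline's readers.
    """
    import os

    from lxml import etree

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "articles": os.path.join(outdir, "articles.xml"),
        "mesh": os.path.join(outdir, "mesh.tsv"),
        "domains": os.path.join(outdir, "domains.yaml"),
        "dictionary": os.path.join(outdir, "dictionary.tsv"),
    }
    root = etree.Element("PubmedArticleSet")
    for d in corpus.documents:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = d.pmid
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = d.title
        ab = etree.SubElement(article, "Abstract")
        etree.SubElement(ab, "AbstractText").text = d.abstract
        mh = etree.SubElement(cit, "MeshHeadingList")
        for mid in d.mesh_ids:
            h = etree.SubElement(mh, "MeshHeading")
            dn = etree.SubElement(h, "DescriptorName")
            dn.set("UI", mid)
            dn.text = corpus.mesh_tree.names.get(mid, mid)
    etree.ElementTree(root).write(
        paths["articles"], pretty_print=True, xml_declaration=True,
        encoding="UTF-8",
    )
    mesh_rows = [
        {
            "descriptor_id": did,
            "name": corpus.mesh_tree.names[did],
            "tree_numbers": ";".join(sorted(corpus.mesh_tree.tree_numbers[did])),
        }
        for did in sorted(corpus.mesh_tree.tree_numbers)
    ]
    pd.DataFrame(mesh_rows).to_csv(paths["mesh"], sep="\t", index=False)
    with open(paths["domains"], "w") as fh:
        for s in corpus.domain_specs:
            fh.write(f"{s.name}: [{', '.join(sorted(s.roots))}]\n")
    dict_rows = [
        {
            "uniprot_id": e.uniprot_id,
            "gene_symbol": e.gene_symbol,
            "synonyms": "|".join(e.synonyms),
        }
        for e in corpus.lexicon.entries
    ]
    pd.DataFrame(dict_rows).to_csv(paths["dictionary"], sep="\t", index=False)
    return paths


def write_expression_files(
    table: ExpressionTable, outdir: str
) -> dict[str, str]:
    """Write the wide expression TSV (rows = proteins) and the group TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
    }
    table.values.T.to_csv(paths["expression"], sep="\t")
    table.groups.rename("group").to_csv(paths["groups"], sep="\t")
    return paths
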