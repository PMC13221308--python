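"""Shared fixtures: a hand-written article-set XML, a tiny MeSH table, a
small protein dictionary, and naive oracle implementations used to
cross-check counting and scoring."""

from __future__ import annotations

import io
import math

import pytest

from litcube.corpus import Document, DomainSpec, MeshTree
from litcube.lexicon import Lexicon, ProteinEntry, normalize_text, _TOKEN

ARTICLES_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1001</PMID>
      <Article>
        <ArticleTitle>BNP in cardiomyopathy</ArticleTitle>
        <Abstract>
          <AbstractText>BNP and pro-BNP rose in heart failure.</AbstractText>
        </Abstract>
      </Article>
      <MeshHeadingList>
        <MeshHeading>
          <DescriptorName UI="D009202">Cardiomyopathies</DescriptorName>
        </MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1002</PMID>
      <Article>
        <ArticleTitle>Renin without abstract</ArticleTitle>
      </Article>
      <MeshHeadingList>
        <MeshHeading>
          <DescriptorName UI="D017202">Myocardial Ischemia</DescriptorName>
        </MeshHeading>
      </MeshHeadingList>
      <KeywordList>
        <Keyword>renin</Keyword>
      </KeywordList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""

MALFORMED_PMID_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle><MedlineCitation><PMID>1</PMID>
    <Article><ArticleTitle>a</ArticleTitle></Article>
  </MedlineCitation></PubmedArticle>
  <PubmedArticle><MedlineCitation>
    <Article><ArticleTitle>no pmid here</ArticleTitle></Article>
  </MedlineCitation></PubmedArticle>
  <PubmedArticle><MedlineCitation><PMID>3</PMID>
    <Article><ArticleTitle>c</ArticleTitle></Article>
  </MedlineCitation></PubmedArticle>
</PubmedArticleSet>
"""

MESH_TSV = """descriptor_id\tname\ttree_numbers
D009202\tCardiomyopathies\tC14.280.238
D017202\tMyocardial Ischemia\tC14.280.647
D002318\tCardiovascular Diseases\tC14
D006331\tHeart Diseases\tC14.280
D003920\tDiabetes Mellitus\tC18.452.394
"""

DICT_TSV = """uniprot_id\tgene_symbol\tsynonyms
P16860\tNPPB\tBNP|pro-BNP|brain natriuretic peptide
P00797\tREN\trenin
P12821\tACE\tangiotensin converting enzyme|ACE
"""


@pytest.fixture
def articles_xml() -> io.BytesIO:
    return io.BytesIO(ARTICLES_XML.encode())


@pytest.fixture
def malformed_pmid_xml() -> io.BytesIO:
    return io.BytesIO(MALFORMED_PMID_XML.encode())


@pytest.fixture
def mesh_tree() -> MeshTree:
    from litcube.corpus import read_mesh_table

    return read_mesh_table(io.StringIO(MESH_TSV))


@pytest.fixture
def dict_tsv() -> io.StringIO:
    return io.StringIO(DICT_TSV)


@pytest.fixture
def heart_domains() -> list[DomainSpec]:
    return [
        DomainSpec(name="heart", roots=frozenset({"D006331"})),
        DomainSpec(name="diabetes", roots=frozenset({"D003920"})),
    ]


@pytest.fixture
def bnp_lexicon() -> Lexicon:
    return Lexicon(
        [
            ProteinEntry("P1", "NPPB", ("bnp", "pro bnp")),
            ProteinEntry("P2", "NPR1", ("bnp receptor",)),
        ]
    )


def doc(pmid: str, text: str = "", mesh: list[str] | None = None) -> Document:
    return Document(pmid=pmid, title="", abstract=text, mesh_ids=mesh or [])


# ---------------------------------------------------------------------------
# independent naive oracles (used by oracle-equivalence tests only)


def naive_count(text: str, lex: Lexicon) -> dict[str, int]:
    """Brute-force leftmost-longest token scan, independent of the trie."""
    tokens = _TOKEN.findall(normalize_text(text))
    syns = sorted(lex.synonym_index.items(), key=lambda kv: -len(kv[0]))
    counts: dict[str, int] = {}
    i = 0
    while i < len(tokens):
        for toks, ids in syns:
            if tuple(tokens[i : i + len(toks)]) == toks:
                for uid in ids:
                    counts[uid] = counts.get(uid, 0) + 1
                i += len(toks)
                break
        else:
            i += 1
    return counts


def naive_scores(
    per_doc_counts: dict[str, dict[str, int]],
    cell_members: dict[str, set[str]],
) -> dict[tuple[str, str], dict[str, float]]:
    """Naive recount/rescore: plain dict-and-math reimplementation.

    per_doc_counts: pmid -> {protein: tf}; cell_members: cell -> pmids.
    Returns (protein, cell) -> component scores for pairs with tf > 0.
    """
    cells = sorted(cell_members)
    tf: dict[tuple[str, str], int] = {}
    for c, pmids in cell_members.items():
        for pmid in pmids:
            for uid, n in per_doc_counts.get(pmid, {}).items():
                tf[(uid, c)] = tf.get((uid, c), 0) + n
    cntP = {c: sum(v for (u, cc), v in tf.items() if cc == c) for c in cells}
    proteins = sorted({u for (u, _c) in tf})
    out: dict[tuple[str, str], dict[str, float]] = {}
    for u in proteins:
        rels = {
            c: (tf.get((u, c), 0) / cntP[c]) if cntP[c] else 0.0 for c in cells
        }
        total = sum(rels.values())
        if total == 0:
            continue
        for c in cells:
            t = tf.get((u, c), 0)
            if t == 0:
                continue
            pop = math.log1p(t) / math.log1p(cntP[c]) if cntP[c] else 0.0
            dist = rels[c] / total
            out[(u, c)] = {
                "integrity": 1.0,
                "popularity": pop,
                "distinctiveness": dist,
                "score": pop * dist,
                "tf": t,
            }
    return out
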