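"""Protein dictionary loading, synonym normalization, and mention counting.

The dictionary is a curated UniProt-style export: accession, gene symbol,
and a pipe-separated list of protein-name synonyms and abbreviations.
Synonyms are normalized (Unicode NFKC, lower-case, hyphens to spaces,
whitespace collapsed) and indexed; a synonym claimed by more than one
protein is ambiguous and dropped from the index by default, so that
paralogs sharing an abbreviation do not inflate each other's attribution.

Matching is dictionary-only (no novel phrase discovery), token-boundary
anchored on the normalized text, leftmost-longest and non-overlapping:
with both "bnp" and "bnp receptor" in the dictionary the text
"bnp receptor" yields one match for the longer phrase.  Counts are per
occurrence, not per document — the popularity component of the composite
score depends on total phrase frequencies.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from litcube.corpus import Document

logger = logging.getLogger(__name__)

_HYPHENS = re.compile(r"[-‐‑‒–—−]")
_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"[0-9a-z]+")


@dataclass(frozen=True)
class ProteinEntry:
    """One dictionary protein: accession, gene symbol, name synonyms."""

    uniprot_id: str
    gene_symbol: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError(
                f"{self.uniprot_id}: at least one synonym required"
            )


def normalize_text(s: str) -> str:
    """Normalize text for matching; idempotent.

    NFKC compatibility normalization, lower-casing, all hyphen variants to
    spaces, whitespace collapsed and stripped.
    """
    s = unicodedata.normalize("NFKC", s).lower()
    s = _HYPHENS.sub(" ", s)
    return _WS.sub(" ", s).strip()


class Lexicon:
    """Compiled synonym index supporting leftmost-longest phrase matching.

    The index maps normalized synonyms (as token tuples) to accessions and
    is compiled into a token trie.  ``dropped_ambiguous`` lists normalized
    synonyms removed because they mapped to more than one protein (unless
    ``allow_ambiguous`` multi-assigns them instead).
    """

    def __init__(
        self,
        entries: list[ProteinEntry],
        allow_ambiguous: bool = False,
    ) -> None:
        self.entries = entries
        self.dropped_ambiguous: list[str] = []
        # normalized synonym -> set of accessions claiming it
        claims: dict[tuple[str, ...], set[str]] = {}
        for e in entries:
            for syn in e.synonyms:
                toks = tuple(_TOKEN.findall(normalize_text(syn)))
                if toks:
                    claims.setdefault(toks, set()).add(e.uniprot_id)
        self.synonym_index: dict[tuple[str, ...], tuple[str, ...]] = {}
        for toks, ids in claims.items():
            if len(ids) == 1 or allow_ambiguous:
                self.synonym_index[toks] = tuple(sorted(ids))
            else:
                self.dropped_ambiguous.append(" ".join(toks))
        self.dropped_ambiguous.sort()
        if self.dropped_ambiguous:
            logger.warning(
                "lexicon: dropped %d ambiguous synonym(s): %s",
                len(self.dropped_ambiguous),
                ", ".join(self.dropped_ambiguous[:10]),
            )
        # token trie: nested dicts; None key holds terminal accession tuple
        self._trie: dict = {}
        for toks, ids in self.synonym_index.items():
            node = self._trie
            for t in toks:
                node = node.setdefault(t, {})
            node[None] = ids

    def __len__(self) -> int:
        return len(self.synonym_index)

    def match_tokens(self, tokens: list[str]) -> list[tuple[int, int, tuple[str, ...]]]:
        """Leftmost-longest non-overlapping matches over a token sequence.

        Returns (start, end, accessions) triples with end exclusive.
        """
        out = []
        i, n = 0, len(tokens)
        while i < n:
            node = self._trie
            best_end, best_ids = -1, None
            j = i
            while j < n and tokens[j] in node:
                node = node[tokens[j]]
                j += 1
                if None in node:
                    best_end, best_ids = j, node[None]
            if best_ids is not None:
                out.append((i, best_end, best_ids))
                i = best_end
            else:
                i += 1
        return out


def load_lexicon(
    table: str | IO[str], allow_ambiguous: bool = False
) -> Lexicon:
    """Load a dictionary TSV: uniprot_id, gene_symbol, synonyms (pipe-sep).

    The gene symbol is always included as a synonym.  Duplicate accessions
    or an empty table raise ValueError.
    """
    df = pd.read_csv(table, sep="\t", dtype=str).fillna("")
    required = {"uniprot_id", "gene_symbol", "synonyms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dictionary missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty protein dictionary")
    if df["uniprot_id"].duplicated().any():
        dups = sorted(df.loc[df["uniprot_id"].duplicated(), "uniprot_id"])
        raise ValueError(f"duplicate uniprot_id rows: {dups}")
    entries = []
    for row in df.itertuples(index=False):
        syns = [s.strip() for s in row.synonyms.split("|") if s.strip()]
        if row.gene_symbol.strip():
            syns.append(row.gene_symbol.strip())
        entries.append(
            ProteinEntry(
                uniprot_id=row.uniprot_id.strip(),
                gene_symbol=row.gene_symbol.strip(),
                synonyms=tuple(dict.fromkeys(syns)),
            )
        )
    return Lexicon(entries, allow_ambiguous=allow_ambiguous)


def count_mentions(doc: Document, lex: Lexicon) -> dict[str, int]:
    """Occurrence counts per accession in one document's searchable text.

    Scans the concatenation of title, abstract and keywords; matches are
    leftmost-longest, non-overlapping, token-boundary anchored on the
    normalized text.  Absent accessions mean zero.
    """
    tokens = _TOKEN.findall(normalize_text(doc.text))
    counts: Counter[str] = Counter()
    for _s, _e, ids in lex.match_tokens(tokens):
        for uid in ids:
            counts[uid] += 1
    return dict(counts)


def count_corpus_mentions(
    docs: Iterable[Document], lex: Lexicon
) -> pd.DataFrame:
    """Long-format mention table over a corpus: pmid, uniprot_id, tf.

    Only pairs with tf >= 1 are recorded.
    """
    rows = []
    for doc in docs:
        for uid, tf in count_mentions(doc, lex).items():
            rows.append((doc.pmid, uid, tf))
    return pd.DataFrame(rows, columns=["pmid", "uniprot_id", "tf"]).astype(
        {"pmid": str, "uniprot_id": str, "tf": int}
    )
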