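"""End-to-end pipeline wiring: configuration, stage ordering, manifest.

Stages run in order corpus -> lexicon -> scoring -> prioritize -> stats ->
validate; every stage's outputs are written before the next starts, and a
run manifest records the package version, all effective parameters, input
checksums and any warnings surfaced along the way (ambiguous synonyms,
tissue ties, degenerate cutoffs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from litcube import __version__
from litcube.corpus import (
    assign_domains,
    deduplicate,
    read_domain_config,
    read_medline_xml,
    read_mesh_table,
    shared_document_matrix,
)
from litcube.lexicon import count_corpus_mentions, load_lexicon
from litcube.prioritize import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_LOOSE_FRACTION,
    DEFAULT_SMOOTH_WINDOW,
    classify_attributions,
    derive_cutoffs,
    overlap_sets,
    top_k,
)
from litcube.scoring import score_corpus
from litcube.stats import cross_domain_regression, summarize_scores
from litcube.validate import (
    DEFAULT_BACKGROUND_N,
    ExpressionTable,
    differential_rank,
    overlap_enrichment,
    tissue_max_assignment,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any compute when the run configuration is invalid."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    All input paths must exist at run start; every effective default is
    echoed into the run manifest.
    """

    articles: str
    mesh: str
    dictionary: str
    domains: str
    outdir: str
    expression: str | None = None
    groups: str | None = None
    tissue: str | None = None
    bin_width: float = DEFAULT_BIN_WIDTH
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    loose_fraction: float = DEFAULT_LOOSE_FRACTION
    top_k: int = 20
    background_n: int = DEFAULT_BACKGROUND_N
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate_paths(self) -> None:
        required = {
            "articles": self.articles,
            "mesh": self.mesh,
            "dictionary": self.dictionary,
            "domains": self.domains,
        }
        optional = {
            "expression": self.expression,
            "groups": self.groups,
            "tissue": self.tissue,
        }
        for name, path in {**required, **optional}.items():
            if path is None:
                continue
            if not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")
        if (self.expression is None) != (self.groups is None):
            raise ConfigError(
                "expression and groups must be supplied together"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written).

    Any stage failure propagates with the stage name prepended so the
    operator knows which input to inspect.
    """
    config.validate_paths()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "extra"
        },
        "inputs": {},
        "warnings": [],
        "stages": [],
    }
    for name in ("articles", "mesh", "dictionary", "domains",
                 "expression", "groups", "tissue"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    try:
        stage = "corpus"
        docs = deduplicate(read_medline_xml(config.articles))
        tree = read_mesh_table(config.mesh)
        specs = read_domain_config(config.domains)
        cells = assign_domains(docs, tree, specs)
        shared_document_matrix(cells).to_csv(
            out("shared_documents.tsv"), sep="\t"
        )
        manifest["stages"].append(stage)

        stage = "lexicon"
        lex = load_lexicon(config.dictionary)
        if lex.dropped_ambiguous:
            manifest["warnings"].append(
                f"lexicon: dropped ambiguous synonyms: {lex.dropped_ambiguous}"
            )
        mentions = count_corpus_mentions(docs, lex)
        mentions.attrs["known_pmids"] = {d.pmid for d in docs}
        mentions.to_csv(out("mentions.tsv"), sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "scoring"
        table = score_corpus(mentions, cells)
        table.to_csv(out("scores.tsv"), sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "prioritize"
        cutoffs = derive_cutoffs(
            table, bin_width=config.bin_width,
            smooth_window=config.smooth_window,
        )
        pd.DataFrame(
            [
                {"cell": c, "cutoff": r.cutoff, "degenerate": r.degenerate}
                for c, r in sorted(cutoffs.items())
            ]
        ).to_csv(out("cutoffs.tsv"), sep="\t", index=False)
        for c, r in cutoffs.items():
            if r.degenerate:
                manifest["warnings"].append(f"degenerate cutoff in {c}")
        classes = classify_attributions(
            table, cutoffs, loose_fraction=config.loose_fraction
        )
        classes.to_csv(out("attributions.tsv"), sep="\t", index=False)
        cell_names = sorted(table["cell"].unique())
        rankings = {
            c: top_k(table, c, config.top_k) for c in cell_names
        }
        with open(out("top_k.json"), "w") as fh:
            json.dump(rankings, fh, indent=1)
        if len(cell_names) >= 2:
            regions, shared_mat = overlap_sets(table, cell_names)
            with open(out("venn_regions.json"), "w") as fh:
                json.dump(
                    {"|".join(sorted(k)): v for k, v in regions.items()},
                    fh, indent=1, sort_keys=True,
                )
            shared_mat.to_csv(out("shared_proteins.tsv"), sep="\t")
        manifest["stages"].append(stage)

        stage = "stats"
        summaries = {
            c: asdict(summarize_scores(table, c)) for c in cell_names
        }
        with open(out("score_summaries.json"), "w") as fh:
            json.dump(summaries, fh, indent=1, sort_keys=True)
        if len(cell_names) >= 2:
            reg_rows = []
            cx = cell_names[0]
            for cy in cell_names[1:]:
                try:
                    r = cross_domain_regression(table, cx, cy)
                except ValueError:
                    continue
                reg_rows.append({"cell_x": cx, "cell_y": cy, **asdict(r)})
            pd.DataFrame(reg_rows).to_csv(
                out("regressions.tsv"), sep="\t", index=False
            )
        manifest["stages"].append(stage)

        stage = "validate"
        if config.expression and config.groups:
            expr = ExpressionTable.from_tsv(config.expression, config.groups)
            ranked = differential_rank(expr)
            ranked.to_csv(out("differential.tsv"), sep="\t", index=False)
            lit_list = rankings[cell_names[0]]
            enr = overlap_enrichment(
                lit_list,
                list(expr.values.columns),
                background_n=config.background_n,
            )
            with open(out("enrichment.json"), "w") as fh:
                json.dump(asdict(enr), fh, indent=1)
        if config.tissue:
            tissue = pd.read_csv(config.tissue, sep="\t")
            profile = tissue_max_assignment(
                tissue, rankings[cell_names[0]]
            )
            profile.tissue_counts.rename("count").to_csv(
                out("tissue_counts.tsv"), sep="\t"
            )
            if profile.not_detected:
                manifest["warnings"].append(
                    f"tissue: not detected: {profile.not_detected}"
                )
        manifest["stages"].append(stage)
    except ConfigError:
        raise
    except Exception as exc:  # surface the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
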