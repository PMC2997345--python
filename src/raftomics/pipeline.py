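"""End-to-end orchestration of the two-condition profiling workflow.

``run_full`` drives: identification filtering -> replicate consensus ->
spectral-count ratios -> whole-proteome overlap -> pathway enrichment and
subtractive differential per category -> LSI score matrices with the
multidimensional filter and cumulative term scores -> receptor-subset
overlap -> interaction-network scoring.  Every stage writes plain TSV and
a JSON run manifest records parameters, versions, seeds and input hashes;
optional stages (literature, network) are skipped with a warning when
their inputs are absent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, enrichment, filtering, lsi, network, sets
from .core import (
    AliasMap,
    ConditionDataset,
    read_category_map,
    read_gene_sets,
    read_protein_table,
    write_tsv,
)
from .filtering import FilterPolicy

logger = logging.getLogger("raftomics")

DATA_DIR = Path(__file__).parent / "data"
RECEPTOR_TYPES = ("transmembrane receptor", "g-protein coupled receptor")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; YAML-loadable via ``from_yaml``."""

    protein_table: Path
    out_dir: Path
    control_label: str = "control"
    case_label: str = "case"
    gene_sets: Path | None = None
    category_map: Path | None = None
    aliases: Path | None = None
    corpus: Path | None = None
    graph: Path | None = None
    receptor_annotation: Path | None = None
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    ratio_scale: str = "fraction"
    pseudocount: float = 0.5
    top_n: int = 50
    lsi_k: int = 300
    lsi_weighting: str = "log-entropy"
    lsi_threshold: float = 0.1
    min_terms: int = 2
    interrogation_terms: tuple[str, ...] = lsi.DEFAULT_INTERROGATION_TERMS
    network_max_size: int = 35
    n_candidates: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        policy = FilterPolicy(**raw.pop("policy", {}))
        for key in ("protein_table", "out_dir", "gene_sets", "category_map",
                    "aliases", "corpus", "graph", "receptor_annotation"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "interrogation_terms" in raw:
            raw["interrogation_terms"] = tuple(raw["interrogation_terms"])
        return cls(policy=policy, **raw)


def load_receptor_annotation(path: str | Path | None = None) -> pd.DataFrame:
    """Receptor-type annotation table; defaults to the packaged two-condition
    receptor fixture (symbol, condition, protein_type, location)."""
    p = Path(path) if path is not None else DATA_DIR / "receptor_tables.tsv"
    if not p.exists():
        raise FileNotFoundError(f"receptor annotation file not found: {p}")
    df = pd.read_csv(p, sep="\t")
    df["symbol"] = df["symbol"].str.strip().str.upper()
    return df


def fixture_receptor_sets() -> tuple[set[str], set[str]]:
    """The packaged control / case receptor symbol sets (47 and 30 symbols)."""
    df = load_receptor_annotation()
    ctrl = set(df.loc[df["condition"] == "control", "symbol"])
    case = set(df.loc[df["condition"] == "case", "symbol"])
    return ctrl, case


def filter_receptor_subset(
    dataset: ConditionDataset, annotation: pd.DataFrame
) -> ConditionDataset:
    """Restrict a consensus set to symbols annotated as receptors."""
    if "symbol" not in annotation.columns or "protein_type" not in annotation.columns:
        raise ValueError("annotation needs 'symbol' and 'protein_type' columns")
    receptors = set(
        annotation.loc[
            annotation["protein_type"].str.lower().isin(RECEPTOR_TYPES), "symbol"
        ].str.upper()
    )
    kept = dataset.consensus_symbols & receptors
    dropped = dataset.consensus_symbols - receptors
    if not kept:
        logger.warning("receptor filter left no symbols for %s", dataset.condition)
    if dropped:
        logger.info("receptor filter dropped %d non-receptor symbols", len(dropped))
    return ConditionDataset(
        condition=dataset.condition,
        replicates=list(dataset.replicates),
        consensus_symbols=kept,
        spectral_counts={s: dataset.spectral_counts.get(s, 0) for s in kept},
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _overlap_frame(ov: sets.OverlapStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("size_a", ov.size_a), ("size_b", ov.size_b), ("common", ov.common),
            ("union", ov.union_size),
            ("commonality_percent", ov.rounded_percent()),
        ],
        columns=["quantity", "value"],
    )


def run_full(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the run manifest.

    A stage failure aborts the run with the stage name and cause; tables
    already written are retained next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": [],
    }
    for key in ("protein_table", "gene_sets", "category_map", "aliases", "corpus", "graph"):
        p = getattr(config, key)
        if p is not None and Path(p).exists():
            manifest["inputs"][key] = _sha256(Path(p))

    stage = "setup"
    try:
        aliases = AliasMap.from_tsv(config.aliases) if config.aliases else None

        stage = "filter-consensus"
        records = read_protein_table(config.protein_table, aliases)
        kept = filtering.filter_identifications(records, config.policy)
        control = filtering.consensus_set(kept, config.control_label, config.policy)
        case = filtering.consensus_set(kept, config.case_label, config.policy)
        manifest["stages"].append(stage)

        stage = "overlap"
        ov = sets.overlap_stats(case.consensus_symbols, control.consensus_symbols)
        write_tsv(_overlap_frame(ov), out / "overlap.tsv",
                  {"a": config.case_label, "b": config.control_label})
        manifest["commonality_percent"] = ov.rounded_percent()
        manifest["stages"].append(stage)

        stage = "spectral-ratios"
        ratios = filtering.spectral_ratio(case, control, pseudocount=config.pseudocount)
        up, down = filtering.rank_differential(ratios, top_n=config.top_n)
        write_tsv(filtering.ratios_to_frame(up, down), out / "spectral_ratios.tsv",
                  {"pseudocount": config.pseudocount, "top_n": config.top_n})
        manifest["stages"].append(stage)

        if config.gene_sets is not None:
            stage = "enrichment"
            cat_map = read_category_map(config.category_map) if config.category_map else None
            collection = read_gene_sets(config.gene_sets, category_map=cat_map, aliases=aliases)
            collection.extend_universe(case.consensus_symbols | control.consensus_symbols)
            case_res = enrichment.enrich(case, collection, ratio_scale=config.ratio_scale)
            ctrl_res = enrichment.enrich(control, collection, ratio_scale=config.ratio_scale)
            diffs = enrichment.differential_profile(case_res, ctrl_res)
            write_tsv(enrichment.results_to_frame(case_res, ctrl_res, diffs),
                      out / "enrichment.tsv", {"ratio_scale": config.ratio_scale})
            for cat in sorted({d.category for d in diffs}):
                report = enrichment.category_report(diffs, cat)
                write_tsv(report, out / f"differential_{cat}.tsv", {"category": cat})
            manifest["n_passing_sets"] = len(diffs)
            manifest["stages"].append(stage)
        else:
            logger.warning("no gene-set file configured; skipping enrichment stage")

        if config.corpus is not None:
            stage = "lsi"
            corpus = lsi.Corpus.from_jsonl(config.corpus, stopwords=lsi.default_stopwords())
            model = lsi.build_index(corpus, k=config.lsi_k, weighting=config.lsi_weighting)
            all_genes = sorted(case.consensus_symbols | control.consensus_symbols)
            model.gene_doc_map = lsi.map_genes_to_documents(corpus, all_genes, aliases)
            case_scores = lsi.score_matrix(
                model, sorted(case.consensus_symbols),
                terms=config.interrogation_terms, threshold=config.lsi_threshold)
            ctrl_scores = lsi.score_matrix(
                model, sorted(control.consensus_symbols),
                terms=config.interrogation_terms, threshold=config.lsi_threshold)
            filt = lsi.multidimensional_filter(
                case_scores, ctrl_scores,
                threshold=config.lsi_threshold, min_terms=config.min_terms)
            write_tsv(filt.kept, out / "lsi_heatmap.tsv",
                      {"threshold": config.lsi_threshold, "min_terms": config.min_terms})
            write_tsv(filt.per_term_unique_counts, out / "lsi_term_counts.tsv", {})
            cum = pd.DataFrame(
                [
                    (t, lsi.cumulative_score(case_scores, t), lsi.cumulative_score(ctrl_scores, t))
                    for t in config.interrogation_terms
                ],
                columns=["term", "cumulative_case", "cumulative_control"],
            )
            write_tsv(cum, out / "lsi_cumulative.tsv", {})
            manifest["stages"].append(stage)
        else:
            logger.warning("no corpus configured; skipping LSI stage")

        stage = "receptor-subset"
        annotation = load_receptor_annotation(config.receptor_annotation)
        case_rec = filter_receptor_subset(case, annotation)
        ctrl_rec = filter_receptor_subset(control, annotation)
        if case_rec.consensus_symbols or ctrl_rec.consensus_symbols:
            ov_rec = sets.overlap_stats(case_rec.consensus_symbols, ctrl_rec.consensus_symbols)
            write_tsv(_overlap_frame(ov_rec), out / "receptor_overlap.tsv", {})
            manifest["receptor_commonality_percent"] = ov_rec.rounded_percent()
        manifest["stages"].append(stage)

        if config.graph is not None:
            stage = "network"
            graph = network.read_interaction_graph(config.graph)
            focus = (case_rec.consensus_symbols or case.consensus_symbols) & set(graph.nodes)
            if focus:
                cands = network.generate_candidate_networks(
                    graph, focus, max_size=config.network_max_size,
                    n_candidates=config.n_candidates, seed=config.seed)
                write_tsv(pd.DataFrame(network.scores_to_rows(cands)),
                          out / "network_scores.tsv",
                          {"generator": network.GENERATOR_LABEL})
                manifest["top_network_score"] = cands[0].score
            else:
                logger.warning("no focus molecule in graph; skipping network stage")
            manifest["stages"].append(stage)
        else:
            logger.warning("no interaction graph configured; skipping network stage")

    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
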