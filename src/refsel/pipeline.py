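"""End-to-end orchestration: read -> normalize -> REFS -> rules -> evaluation.

Every run writes a self-describing run directory: the reduction traces, the
consensus signature, the extracted rule set, pooled-fold ROC curves and
AUCs, the two-track gene overlap report, a heatmap-ready signature matrix,
and a manifest with the fully resolved configuration.  Each artifact starts
with a comment line naming the configuration hash and global seed that
produced it, and identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate as ev
from . import io as rio
from . import refs as rf
from . import rules as rl
from . import synth as sy
from .exceptions import StageError

logger = logging.getLogger("refsel")


@dataclass(frozen=True)
class RuleParams:
    max_len: int = 3
    top_k_concepts: int = 10
    min_precision: float = 0.8
    coverage_target: float = 0.95


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run.

    Either ``matrix_path``/``labels_path`` point at input files, or
    ``synth`` describes a cohort to simulate in place of them.
    """

    matrix_path: str | None = None
    labels_path: str | None = None
    probe_map_path: str | None = None
    #: map probe ids to gene ids on the whole matrix after reading, instead
    #: of the default short-list mapping of the final signature / rule genes
    map_upfront: bool = False
    dialect: str = "tsv"
    synth: sy.SynthConfig | None = None
    refs: rf.RefsConfig = field(default_factory=rf.RefsConfig)
    rules: RuleParams = field(default_factory=RuleParams)
    seed: int = 0

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.resolved(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("load")
def _load(cfg: PipelineConfig):
    if cfg.synth is not None:
        matrix, labels, _truth = sy.generate_cohort(cfg.synth)
        return matrix, labels
    if cfg.matrix_path is None or cfg.labels_path is None:
        raise ValueError("either synth or matrix_path+labels_path must be set")
    matrix = rio.read_expression_matrix(cfg.matrix_path, dialect=cfg.dialect)
    if cfg.probe_map_path and cfg.map_upfront:
        matrix = rio.map_probes(matrix, rio.read_probe_map(cfg.probe_map_path))
    labels = rio.read_labels(cfg.labels_path)
    labels = rio.encode_labels(labels.groups, list(matrix.columns))
    return matrix, labels


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full two-track analysis and write the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    header = f"# config_hash={chash} seed={cfg.seed}\n"

    matrix, labels = _load(cfg)
    normalized = _normalize(matrix)
    patients = labels.patient_ids
    X_pat = normalized[patients]
    y = labels.y.to_numpy()

    traces, k_star, signature = _refs_stage(X_pat, y, cfg)
    _write_tsv(outdir / "trace.tsv", rf.traces_to_frame(traces), header)
    _write_tsv(outdir / "signature.tsv", rf.signature_to_frame(signature, traces), header)

    ruleset = _rules_stage(normalized, labels, cfg)
    (outdir / "rules.txt").write_text(header + rl.format_ruleset(ruleset))

    roc, overlap = _evaluate_stage(X_pat, y, normalized, labels, signature, ruleset, cfg)
    points, summary = ev.roc_to_frames(roc)
    _write_tsv(outdir / "roc_curves.tsv", points, header)
    _write_tsv(outdir / "roc_auc.tsv", summary, header)
    (outdir / "overlap.txt").write_text(header + ev.format_overlap(overlap))

    sig_matrix = ev.export_signature_matrix(normalized, labels, signature)
    with open(outdir / "signature_matrix.tsv", "w") as fh:
        fh.write(header)
        sig_matrix.to_csv(fh, sep="\t", index_label="gene_id")

    manifest = {
        "config_hash": chash,
        "seed": cfg.seed,
        "config": cfg.resolved(),
        "run_seeds": rf.derive_run_seeds(cfg.refs.seed, cfg.refs.n_runs),
        "k_star": int(k_star),
        "signature": list(signature.gene_ids),
        "rule_genes": sorted(ruleset.genes),
        "overlap": overlap.counts,
        "auc": roc.auc,
    }
    if cfg.probe_map_path and not cfg.map_upfront:
        # default short-list mapping: probe ids are translated only for the
        # final selected genes, never for the full matrix
        pm = rio.read_probe_map(cfg.probe_map_path)
        manifest["signature_mapped"] = [pm.get(g, g) for g in signature.gene_ids]
        manifest["rule_genes_mapped"] = sorted(pm.get(g, g) for g in ruleset.genes)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    logger.info("pipeline complete: %s (k*=%d)", outdir, k_star)
    return outdir


@_stage("normalize")
def _normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    return rio.zscore_normalize(matrix)


@_stage("refs")
def _refs_stage(X_pat, y, cfg: PipelineConfig):
    traces = rf.run_refs_ensemble(X_pat, y, cfg.refs)
    k_star = rf.select_optimal_size(traces)
    signature = rf.consensus_signature(traces, k_star)
    return traces, k_star, signature


@_stage("rules")
def _rules_stage(normalized, labels, cfg: PipelineConfig) -> rl.RuleSet:
    baseline = rl.compute_baseline(normalized, labels)
    concepts = rl.binarize_concepts(normalized, labels, baseline)
    return rl.extract_rules(
        concepts,
        labels.y.to_numpy(),
        max_len=cfg.rules.max_len,
        top_k_concepts=cfg.rules.top_k_concepts,
        min_precision=cfg.rules.min_precision,
        coverage_target=cfg.rules.coverage_target,
        split_seed=cfg.seed,
    )


@_stage("evaluate")
def _evaluate_stage(X_pat, y, normalized, labels, signature, ruleset, cfg: PipelineConfig):
    roc = ev.pooled_cv_roc(X_pat.loc[list(signature.gene_ids)], y, cfg.refs, seed=cfg.seed)
    overlap = ev.signature_overlap(signature, sorted(ruleset.genes))
    return roc, overlap


def _write_tsv(path: Path, frame: pd.DataFrame, header: str):
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def config_from_yaml(path: str | Path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    synth = raw.pop("synth", None)
    refs = raw.pop("refs", None)
    rules = raw.pop("rules", None)
    return PipelineConfig(
        synth=sy.SynthConfig(**synth) if isinstance(synth, dict) else None,
        refs=rf.RefsConfig(**_tupled(refs)) if isinstance(refs, dict) else rf.RefsConfig(),
        rules=RuleParams(**rules) if isinstance(rules, dict) else RuleParams(),
        **raw,
    )


def _tupled(refs: dict) -> dict:
    refs = dict(refs)
    if "roster" in refs:
        refs["roster"] = tuple(refs["roster"])
    return refs
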