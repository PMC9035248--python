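"""End-to-end runs from a single serializable configuration.

A run executes prep -> extract -> balance -> benchmark sequentially and
writes every artifact (feature matrices, long-format results, logs, a
config snapshot and a sha256 checksum manifest) into one directory.
Reruns with an identical config reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .dataset_prep import assemble_dataset, read_fasta
from .evaluation import ClassifierSpec, run_grid
from .feature_extraction import FEATURE_METHODS, build_matrix
from .sampling_balance import SamplingSpec
from .synthetic_data import CorpusSpec, random_corpus

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Raised when a run configuration is invalid (before any work starts)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``simulate`` (a CorpusSpec-shaped mapping) or both
    ``positive_fasta`` and ``negative_fasta`` must be given.
    """

    feature_classes: Sequence[str]
    classifiers: Sequence[str]
    plans: Sequence[str]  # e.g. "kfold:10", "holdout:0.3"
    simulate: Mapping | None = None
    positive_fasta: str | None = None
    negative_fasta: str | None = None
    reduce_redundancy: bool = False
    reduction_threshold: float = 0.25
    balance: Sequence[str] = ("none",)
    seed: int = 0

    def validate(self) -> None:
        if not self.feature_classes:
            raise ConfigError("no feature classes configured")
        unknown = [m for m in self.feature_classes if m not in FEATURE_METHODS]
        if unknown:
            raise ConfigError(f"unknown feature classes {unknown}; available: {sorted(FEATURE_METHODS)}")
        if not self.classifiers:
            raise ConfigError("no classifiers configured")
        for algo in self.classifiers:
            ClassifierSpec(algorithm=algo)  # raises on unknown names
        if not self.plans:
            raise ConfigError("no split plans configured")
        for plan in self.plans:
            parse_plan(plan)
        for mode in self.balance:
            SamplingSpec(mode=mode)
        has_files = self.positive_fasta is not None and self.negative_fasta is not None
        if (self.simulate is None) == (not has_files):
            raise ConfigError("configure exactly one input: 'simulate' or both FASTA paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        config.validate()
        return config


def parse_plan(text: str) -> tuple[str, float]:
    """Parse ``kfold:10`` / ``holdout:0.3`` plan shorthand."""
    try:
        kind, raw = text.split(":", 1)
        param = float(raw)
    except ValueError:
        raise ConfigError(f"bad plan {text!r}; expected 'kfold:K' or 'holdout:FRACTION'") from None
    if kind not in ("kfold", "holdout"):
        raise ConfigError(f"bad plan kind {kind!r}")
    return kind, param


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute a full run and return the output directory.

    Artifacts: ``config.yaml`` (snapshot), ``dataset.json`` (per-class
    counts), one ``features_<class>.csv`` per feature class,
    ``results.csv`` (long format), ``run.log.jsonl`` and
    ``checksums.txt``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log.jsonl"
    log_entries: list[dict] = []

    def log(stage: str, **payload) -> None:
        log_entries.append({"stage": stage, **payload})

    try:
        if config.simulate is not None:
            spec = CorpusSpec(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
            records, labels = random_corpus(spec)
            log("prep", source="simulate", n_pos=spec.n_pos, n_neg=spec.n_neg, seed=spec.seed)
        else:
            pos = read_fasta(config.positive_fasta)
            neg = read_fasta(config.negative_fasta)
            records, labels, summary = assemble_dataset(
                pos,
                neg,
                reduce=config.reduce_redundancy,
                threshold=config.reduction_threshold,
            )
            log("prep", source="fasta", **summary)
    except Exception as exc:
        raise RuntimeError(f"stage 'prep' failed: {exc}") from exc

    with open(outdir / "dataset.json", "w") as handle:
        counts = {label: labels.count(label) for label in sorted(set(labels))}
        json.dump({"n_records": len(records), "class_counts": counts}, handle, indent=2)

    matrices = {}
    for method in config.feature_classes:
        try:
            matrix = build_matrix(records, labels, method)
        except Exception as exc:
            raise RuntimeError(f"stage 'extract' failed for {method!r}: {exc}") from exc
        matrices[method] = matrix
        safe = method.replace(".", "_")
        matrix.to_csv(outdir / f"features_{safe}.csv")
        log("extract", method=method, n_features=len(matrix.feature_names))

    specs = [ClassifierSpec(algorithm=a) for a in config.classifiers]
    plans = [parse_plan(p) for p in config.plans]
    samplings = [SamplingSpec(mode=m, seed=config.seed) for m in config.balance]
    try:
        results = run_grid(matrices, specs, plans, samplings, seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'benchmark' failed: {exc}") from exc
    results.to_csv(outdir / "results.csv", index=False)
    log("benchmark", n_cells=int(results["cell"].nunique()), n_rows=len(results))

    with open(outdir / "config.yaml", "w") as handle:
        # normalize tuples and other sequence types to plain YAML lists
        snapshot = json.loads(json.dumps(asdict(config), default=list))
        yaml.safe_dump(snapshot, handle, sort_keys=True)
    with open(log_path, "w") as handle:
        for entry in log_entries:
            handle.write(json.dumps(entry, sort_keys=True) + "\n")

    manifest = []
    for path in sorted(outdir.iterdir()):
        if path.name == "checksums.txt" or path.is_dir():
            continue
        manifest.append(f"{_sha256(path)}  {path.name}")
    (outdir / "checksums.txt").write_text("\n".join(manifest) + "\n")
    return outdir
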