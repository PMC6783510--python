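"""End-to-end screening pipeline: modules → ranking → mechanisms.

One :class:`RunConfig` (YAML-loadable) drives the whole run and is
hashed into every output header, so a ranking table can always be traced
back to the exact inputs, seed and parameters that produced it. A rerun
with the same config and seed reproduces ``ranking.tsv`` byte for byte.

Profile sources: a directory containing a ``manifest.yaml`` written by
:func:`tfgmr.synthetic_compendium.simulate_compendium` (matrices are
scored with the configured rank metric), or a directory of ``*.rnk``
ranked-list files (one compound each, named after the file stem).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .expression_ranking import (
    RankedGeneList,
    build_ranked_list,
    differential_scores,
    load_expression_matrix,
    read_rnk,
)
from .module_builder import GeneModule, ModulePair, read_gmt, write_gmt
from .enrichment_core import CompoundScore, rank_compounds
from .mechanism_inference import export_bipartite, ora, pairwise_overlap_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_module_pair", "load_profiles"]


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything a screening run depends on.

    universe: ``"modules"`` restricts mechanism tests to the union of
    the two reference modules; ``"measured"`` uses the full gene
    universe of the profiles.
    """

    modules: str
    profiles: str
    out_dir: str
    exponent: float = 1.0
    permutations: int = 1000
    seed: int = 0
    rank_metric: str = "moderated_t"
    alpha: float = 0.05
    universe: str = "modules"
    annotations: str | None = None

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be ≥ 1")
        if self.universe not in ("modules", "measured"):
            raise ValueError("universe must be 'modules' or 'measured'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        for label, p in (("modules", self.modules), ("profiles", self.profiles),
                         ("annotations", self.annotations)):
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{label} path does not exist: {p}")

    def hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_module_pair(path: str | Path) -> ModulePair:
    """Read a 2-set GMT as (positive, negative) module pair.

    GMT carries no core/co-expressed split, so all members are loaded as
    core; enrichment only consumes the member sets.
    """
    sets = read_gmt(path)
    if len(sets) != 2:
        raise ValueError(f"{path}: expected exactly 2 gene sets, found {len(sets)}")
    pos, neg = sets
    return ModulePair(
        positive=GeneModule(pos.name, pos.description, pos.genes, frozenset()),
        negative=GeneModule(neg.name, neg.description, neg.genes, frozenset()),
    )


def load_profiles(profiles_dir: str | Path, rank_metric: str = "moderated_t") -> dict[str, RankedGeneList]:
    """Load compound profiles as ranked lists (see module docstring)."""
    d = Path(profiles_dir)
    manifest_path = d / "manifest.yaml"
    profiles: dict[str, RankedGeneList] = {}
    if manifest_path.exists():
        manifest = yaml.safe_load(manifest_path.read_text())
        for entry in manifest["compounds"]:
            cid = entry["compound_id"]
            matrix = load_expression_matrix(d / entry["matrix"], labels=d / entry["labels"])
            profiles[cid] = build_ranked_list(differential_scores(matrix, method=rank_metric))
        return profiles
    rnks = sorted(d.glob("*.rnk"))
    if not rnks:
        raise ValueError(f"{d}: no manifest.yaml and no *.rnk files")
    for p in rnks:
        profiles[p.stem] = read_rnk(p)
    return profiles


def _header_lines(config: RunConfig) -> str:
    return (
        f"# tfgmr {__version__}\n"
        f"# seed: {config.seed}\n"
        f"# config_hash: {config.hash()}\n"
    )


def write_ranking(scores: list[CompoundScore], path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        fh.write("compound\tes_pfgm\tes_nfgm\ttes\tp_value\trank\n")
        for rank, s in enumerate(scores, 1):
            fh.write(
                f"{s.compound_id}\t{s.es_pfgm:.6g}\t{s.es_nfgm:.6g}\t"
                f"{s.tes:.6g}\t{s.p_value:.6g}\t{rank}\n"
            )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full screen; returns the run directory.

    Stages: validate → load modules → load/rank profiles → score &
    rank compounds → export leading edges → mechanism inference
    (pairwise overlaps among compounds significant at alpha; ORA +
    bipartite export when an annotation GMT is configured) → metadata.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        pair = load_module_pair(config.modules)
        write_gmt(pair, out / "modules.gmt")
    except Exception as e:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("modules", str(e)) from e

    try:
        profiles = load_profiles(config.profiles, rank_metric=config.rank_metric)
    except Exception as e:
        raise PipelineError("profiles", str(e)) from e

    try:
        scores = rank_compounds(
            profiles, pair, B=config.permutations, seed=config.seed,
            exponent=config.exponent,
        )
        write_ranking(scores, out / "ranking.tsv", config)
    except Exception as e:
        raise PipelineError("ranking", str(e)) from e

    le_dir = out / "leading_edges"
    le_dir.mkdir(exist_ok=True)
    regulated: dict[str, set[str]] = {}
    for s in scores:
        (le_dir / f"{s.compound_id}_{pair.positive.name}.txt").write_text(
            "\n".join(s.leading_edge_pfgm) + "\n"
        )
        (le_dir / f"{s.compound_id}_{pair.negative.name}.txt").write_text(
            "\n".join(s.leading_edge_nfgm) + "\n"
        )
        regulated[s.compound_id] = set(s.leading_edge_pfgm) | set(s.leading_edge_nfgm)

    try:
        if config.universe == "modules":
            universe = set(pair.positive.members | pair.negative.members)
        else:
            universe = set().union(*(set(r.genes) for r in profiles.values()))
        significant = [s.compound_id for s in scores if s.p_value < config.alpha]
        if len(significant) >= 2:
            table = pairwise_overlap_table(
                {cid: regulated[cid] & universe for cid in significant}, universe
            )
            table.to_csv(out / "overlap_pvalues.tsv", sep="\t", index=False,
                         float_format="%.6g")
        if config.annotations is not None and significant:
            collection = {s.name: s.genes for s in read_gmt(config.annotations)}
            results = {}
            for cid in significant:
                query = regulated[cid] & universe
                if query:
                    results[cid] = ora(query, collection, universe, alpha=config.alpha)
            df = export_bipartite(results, threshold=config.alpha,
                                  path=out / "bipartite_edges.tsv")
            rows = [
                {"compound": cid, "term_id": r.term_id, "term_size": r.term_size,
                 "overlap": r.overlap, "p_value": r.p_value, "adjusted_p": r.adjusted_p}
                for cid, rs in results.items() for r in rs
            ]
            pd.DataFrame(rows).to_csv(out / "ora_results.tsv", sep="\t", index=False,
                                      float_format="%.6g")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("mechanism", str(e)) from e

    metadata = {
        "tfgmr_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "n_compounds_ranked": len(scores),
        "n_significant": len([s for s in scores if s.p_value < config.alpha]),
        "module_sizes": [len(pair.positive.members), len(pair.negative.members)],
    }
    (out / "run_metadata.yaml").write_text(yaml.safe_dump(metadata, sort_keys=True))
    return out
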