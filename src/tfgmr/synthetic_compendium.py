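"""Synthetic expression compendia with planted module regulation.

Generates desk-scale stand-ins for a compound-treatment microarray
compendium: per compound, a small genes × samples matrix of log-scale
intensities with its own treatment and control groups. Gene baselines
are drawn once per compendium from Normal(7, 1) (typical log2 microarray
intensity scale); sample values add Gaussian noise. A compound planted
as a "vasodilator" shifts the positive-module genes up by the effect
size and the negative-module genes down in its treatment samples (a
"vasoconstrictor" mirrors this; a "null" compound shifts nothing), so
the expected sign and ordering of TES across compounds is known by
construction.

All randomness flows from one master seed; each compound's stream is
derived from a hash of the seed and the compound index, so compendia are
byte-identical across runs and per-compound data do not depend on how
many compounds precede them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .enrichment_core import derive_seed
from .expression_ranking import ExpressionMatrix
from .module_builder import GeneModule, ModulePair, write_gmt

__all__ = ["SyntheticCompendiumSpec", "true_modules", "generate_profiles",
           "simulate_compendium", "truth_manifest"]

DIRECTIONS = ("vasodilator", "vasoconstrictor", "null")


@dataclass(frozen=True)
class SyntheticCompendiumSpec:
    """Parameters of a planted-regulation compendium.

    effect_size is the mean log-expression shift applied to module genes
    in treatment samples of a planted compound (unitless, log2 scale);
    noise_sd the per-measurement Gaussian noise. module_sizes are the
    sizes of the planted positive and negative modules, drawn disjointly
    from the gene universe. planted_profiles maps compound id →
    direction; by default the first compound is a vasodilator and the
    rest are null, mirroring a screen with one true hit.
    """

    n_genes: int = 200
    n_compounds: int = 10
    replicates_per_group: int = 2
    effect_size: float = 1.0
    noise_sd: float = 1.0
    module_sizes: tuple[int, int] = (20, 20)
    planted_profiles: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ValueError("n_genes must be ≥ 4")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be ≥ 1")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be ≥ 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        kp, kn = self.module_sizes
        if kp < 1 or kn < 1:
            raise ValueError("module sizes must be ≥ 1")
        if kp + kn >= self.n_genes:
            raise ValueError(
                f"modules ({kp}+{kn}) must fit strictly inside the {self.n_genes}-gene universe"
            )
        if self.planted_profiles is not None:
            ids = set(self.compound_ids)
            for cid, direction in self.planted_profiles.items():
                if cid not in ids:
                    raise ValueError(f"planted profile for unknown compound {cid!r}")
                if direction not in DIRECTIONS:
                    raise ValueError(f"unknown direction {direction!r} for {cid!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def compound_ids(self) -> list[str]:
        return [f"cpd_{i:03d}" for i in range(self.n_compounds)]

    def direction_of(self, compound_id: str) -> str:
        if self.planted_profiles is not None:
            return self.planted_profiles.get(compound_id, "null")
        return "vasodilator" if compound_id == self.compound_ids[0] else "null"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCompendiumSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "module_sizes" in raw:
            raw["module_sizes"] = tuple(raw["module_sizes"])
        return cls(**raw)


def true_modules(spec: SyntheticCompendiumSpec) -> ModulePair:
    """The planted (disjoint) positive/negative module pair.

    Module gene indices are drawn from the master seed, so modules are a
    function of the spec alone.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "modules"))
    kp, kn = spec.module_sizes
    idx = rng.choice(spec.n_genes, size=kp + kn, replace=False)
    genes = spec.gene_ids
    pos = frozenset(genes[i] for i in idx[:kp])
    neg = frozenset(genes[i] for i in idx[kp : kp + kn])
    return ModulePair(
        positive=GeneModule("PFGM_true", "synthetic:positive", pos, frozenset()),
        negative=GeneModule("NFGM_true", "synthetic:negative", neg, frozenset()),
    )


def _compound_matrix(
    spec: SyntheticCompendiumSpec,
    index: int,
    baseline: np.ndarray,
    pair: ModulePair,
) -> ExpressionMatrix:
    cid = spec.compound_ids[index]
    rng = np.random.default_rng(derive_seed(spec.seed, index))
    r = spec.replicates_per_group
    genes = spec.gene_ids
    shift = np.zeros(spec.n_genes)
    direction = spec.direction_of(cid)
    if direction != "null":
        sign = 1.0 if direction == "vasodilator" else -1.0
        pos_mask = np.fromiter((g in pair.positive.members for g in genes), bool, spec.n_genes)
        neg_mask = np.fromiter((g in pair.negative.members for g in genes), bool, spec.n_genes)
        shift[pos_mask] = sign * spec.effect_size
        shift[neg_mask] = -sign * spec.effect_size
    control = baseline[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, r))
    treatment = (
        baseline[:, None] + shift[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, r))
    )
    samples = [f"{cid}_ctl_{j}" for j in range(r)] + [f"{cid}_trt_{j}" for j in range(r)]
    data = pd.DataFrame(
        np.hstack([control, treatment]), index=genes, columns=samples
    )
    groups = {s: ("control" if "_ctl_" in s else "treatment") for s in samples}
    return ExpressionMatrix(data=data, sample_groups=groups)


def generate_profiles(spec: SyntheticCompendiumSpec) -> dict[str, ExpressionMatrix]:
    """In-memory compendium: compound id → expression matrix."""
    baseline = 7.0 + np.random.default_rng(derive_seed(spec.seed, "baseline")).normal(
        0.0, 1.0, spec.n_genes
    )
    pair = true_modules(spec)
    return {
        cid: _compound_matrix(spec, i, baseline, pair)
        for i, cid in enumerate(spec.compound_ids)
    }


def truth_manifest(spec: SyntheticCompendiumSpec) -> dict:
    """Ground truth as a plain dict (YAML-serialisable)."""
    pair = true_modules(spec)
    return {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "n_compounds": spec.n_compounds,
        "replicates_per_group": spec.replicates_per_group,
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
        "module_sizes": list(spec.module_sizes),
        "compounds": [
            {"compound_id": cid, "direction": spec.direction_of(cid),
             "matrix": f"{cid}.gct", "labels": f"{cid}.cls"}
            for cid in spec.compound_ids
        ],
        "modules": {
            pair.positive.name: sorted(pair.positive.members),
            pair.negative.name: sorted(pair.negative.members),
        },
        "modules_gmt": "true_modules.gmt",
    }


def _write_gct(matrix: ExpressionMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(matrix.gene_ids)}\t{len(matrix.sample_ids)}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.data.iterrows():
            vals = "\t".join(f"{v:.6f}" for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{vals}\n")


def _write_cls(matrix: ExpressionMatrix, path: Path) -> None:
    samples = matrix.sample_ids
    labels = [matrix.sample_groups[s] for s in samples]
    names = ["control", "treatment"]
    with open(path, "w") as fh:
        fh.write(f"{len(samples)} 2 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(names.index(l)) for l in labels) + "\n")


def simulate_compendium(spec: SyntheticCompendiumSpec, out_dir: str | Path) -> Path:
    """Write the compendium to disk; returns the manifest path.

    Emits one GCT + CLS per compound, the true modules as GMT, and a
    YAML manifest tying them together. A fixed spec (seed included)
    yields byte-identical files. The spec is validated before any file
    is written.
    """
    manifest = truth_manifest(spec)  # validates spec & derives truth first
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = generate_profiles(spec)
    for cid, matrix in profiles.items():
        _write_gct(matrix, out / f"{cid}.gct")
        _write_cls(matrix, out / f"{cid}.cls")
    write_gmt(true_modules(spec), out / "true_modules.gmt")
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
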