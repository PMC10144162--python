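"""Tables, file I/O, configuration and the pipeline orchestrator.

All tabular inputs are plain CSV (comma separator, ``.`` decimal point,
header row, UTF-8); trees are Newick with branch lengths.  Validation is
strict: missing columns, non-numeric cells, duplicate keys and
species/tree mismatches raise rather than being silently repaired, because
every downstream covariance or index depends on these values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .trees import PhyloTree, read_tree

__all__ = [
    "DEFAULT_TRAITS",
    "TraitTable",
    "ObservationTable",
    "ProboscisTable",
    "RunConfig",
    "read_trait_table",
    "read_observations",
    "read_tree",
    "run_pipeline",
]

log = logging.getLogger("floralint")

#: canonical floral trait set, all in mm
DEFAULT_TRAITS = (
    "corolla_tube_length",
    "throat_diameter",
    "anther_height",
    "stigma_height",
    "upper_lip_length",
    "upper_lip_width",
    "lower_lip_length",
    "lower_lip_width",
)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s): {missing}")


def _numeric(frame: pd.DataFrame, columns: Sequence[str], what: str) -> pd.DataFrame:
    frame = frame.copy()
    for col in columns:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[parsed.isna() & frame[col].notna()]
        if len(bad) > 0:
            raise FormatError(
                f"{what}: non-numeric value in column '{col}' at row {int(bad[0]) + 2}"
            )
        if parsed.isna().any():
            raise ValidationError(f"{what}: missing value in column '{col}'")
        frame[col] = parsed.astype(float)
    return frame


@dataclass
class TraitTable:
    """Individual-level floral measurements, one row per flower."""

    frame: pd.DataFrame
    trait_names: tuple[str, ...] = DEFAULT_TRAITS

    def __post_init__(self):
        self.trait_names = tuple(self.trait_names)
        _require_columns(self.frame, ("species_id", "individual_id") + self.trait_names, "trait table")
        self.frame = _numeric(self.frame, self.trait_names, "trait table").reset_index(drop=True)
        vals = self.frame[list(self.trait_names)].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("trait values must be finite and > 0")
        key = self.frame[["species_id", "individual_id"]].astype(str)
        dup = key[key.duplicated()].to_records(index=False).tolist()
        if dup:
            raise ValidationError(f"duplicate (species, individual) pairs: {dup[:5]}")
        counts = self.frame.groupby("species_id").size()
        small = sorted(counts[counts < 3].index)
        if small:
            raise ValidationError(
                f"species with fewer than 3 individuals (integration undefined): {small}"
            )

    def species(self) -> list[str]:
        return sorted(self.frame["species_id"].astype(str).unique())

    def values(self) -> np.ndarray:
        return self.frame[list(self.trait_names)].to_numpy(float)

    def species_matrix(self, species_id: str) -> np.ndarray:
        sub = self.frame[self.frame["species_id"] == species_id]
        if sub.empty:
            raise ValidationError(f"unknown species: {species_id}")
        return sub[list(self.trait_names)].to_numpy(float)

    def species_means(self) -> pd.DataFrame:
        return self.frame.groupby("species_id")[list(self.trait_names)].mean()

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ObservationTable:
    """Pollinator visitation records: guild visits per observation period."""

    frame: pd.DataFrame

    def __post_init__(self):
        cols = ("species_id", "guild_id", "period_id", "visits", "open_flowers")
        _require_columns(self.frame, cols, "observation table")
        self.frame = _numeric(self.frame, ("visits", "open_flowers"), "observation table")
        self.frame = self.frame.reset_index(drop=True)
        v = self.frame["visits"]
        f = self.frame["open_flowers"]
        if (v < 0).any() or (v != v.round()).any():
            raise ValidationError("visits must be non-negative integers")
        if (f < 1).any() or (f != f.round()).any():
            raise ValidationError("open_flowers must be integers >= 1")
        self.frame["visits"] = v.astype(int)
        self.frame["open_flowers"] = f.astype(int)

    def species(self) -> list[str]:
        return sorted(self.frame["species_id"].astype(str).unique())

    def guilds(self) -> list[str]:
        return sorted(self.frame["guild_id"].astype(str).unique())

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ProboscisTable:
    """Proboscis-length specimens per pollinator guild (mm)."""

    frame: pd.DataFrame

    def __post_init__(self):
        cols = ("guild_id", "specimen_id", "proboscis_length")
        _require_columns(self.frame, cols, "proboscis table")
        self.frame = _numeric(self.frame, ("proboscis_length",), "proboscis table")
        self.frame = self.frame.reset_index(drop=True)
        x = self.frame["proboscis_length"]
        if not np.all(np.isfinite(x)) or (x <= 0).any():
            raise ValidationError("proboscis lengths must be finite and positive")

    def guilds(self) -> list[str]:
        return sorted(self.frame["guild_id"].astype(str).unique())

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ----------------------------------------------------------------------


def read_trait_table(path: str | Path, trait_names: Sequence[str] = DEFAULT_TRAITS) -> TraitTable:
    """Read and validate an individual-level trait CSV."""
    frame = pd.read_csv(path)
    return TraitTable(frame, tuple(trait_names))


def read_observations(
    obs_path: str | Path, prob_path: str | Path
) -> tuple[ObservationTable, ProboscisTable]:
    """Read visitation records and proboscis measurements; cross-check guilds.

    Guilds that appear in the observations but have no proboscis specimen
    are reported as a warning (their mean length cannot be computed).
    """
    obs = ObservationTable(pd.read_csv(obs_path))
    prob = ProboscisTable(pd.read_csv(prob_path))
    orphans = sorted(set(obs.guilds()) - set(prob.guilds()))
    if orphans:
        log.warning("guilds observed but lacking proboscis specimens: %s", orphans)
    return obs, prob


# ----------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    trait_path: str | None = None
    tree_path: str | None = None
    obs_path: str | None = None
    proboscis_path: str | None = None
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    models: tuple[str, ...] = ("BM", "PL", "OU")
    n_boot: int = 5000
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "integrate", "pla", "pgls", "psem")
    preset: str = "lonicera-like"
    psem_family_file: str | None = None
    out_dir: str = "results"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValidationError("bootstrap replicate count must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        self.trait_names = tuple(self.trait_names)
        self.models = tuple(self.models)
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ----------------------------------------------------------------------
# Pipeline


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so JSON reports are byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis stages and write a JSON + TSV report bundle.

    Stage order: ``simulate`` (or load from the configured paths),
    ``integrate`` (per-species integration index with bootstrap CI),
    ``pla`` (composite proboscis length per species), ``pgls`` (screen of
    integration against each trait and the composite proboscis length under
    the configured evolutionary models), and ``psem`` (candidate path-model
    family, d-separation tests, best-model selection).  Outputs are
    deterministic for a fixed config and seed.
    """
    from . import pollinators as _poll
    from . import pgls as _pgls
    from . import psem as _psem
    from . import synthetic_data as _syn
    from .integration import species_integration

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": int(config.seed), "stages": list(config.stages)}}

    stage = "inputs"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            bundle = _syn.make_dataset(config.preset, seed=config.seed)
            traits, tree = bundle.traits, bundle.tree
            obs, prob = bundle.observations, bundle.proboscis
            bundle.write(out_dir / "synthetic")
        else:
            traits = read_trait_table(config.trait_path, config.trait_names)
            tree = read_tree(config.tree_path)
            obs, prob = read_observations(config.obs_path, config.proboscis_path)
        log.info("inputs ready: %d species, %d tips", len(traits.species()), tree.n_tips)
        tree.check_species(traits.species())

        species_table = traits.species_means()

        if "integrate" in config.stages:
            stage = "integrate"
            int_results = species_integration(traits, n_boot=config.n_boot, seed=config.seed)
            report["integration"] = [r.as_dict() for r in int_results]
            int_frame = pd.DataFrame([r.as_dict() for r in int_results]).drop(columns="eigenvalues")
            int_frame.to_csv(out_dir / "integration.tsv", sep="\t", index=False)
            species_table = species_table.assign(
                percent_int=[r.percent_int for r in int_results]
            )

        if "pla" in config.stages:
            stage = "pla"
            assemblages = _poll.species_assemblages(obs, prob)
            report["pla"] = {
                sp: {"n_guilds": a.n_guilds, "vf_total": a.vf_total, "pla": a.pla}
                for sp, a in sorted(assemblages.items())
            }
            pd.DataFrame(
                [
                    {"species_id": sp, "n_guilds": a.n_guilds, "vf_total": a.vf_total, "pla": a.pla}
                    for sp, a in sorted(assemblages.items())
                ]
            ).to_csv(out_dir / "pla.tsv", sep="\t", index=False)
            species_table = species_table.assign(
                pla=[assemblages[sp].pla for sp in species_table.index]
            )

        passed: list[str] = []
        if "pgls" in config.stages:
            stage = "pgls"
            if "percent_int" not in species_table:
                raise ValidationError("pgls stage requires the integrate stage")
            predictors = list(config.trait_names)
            if "pla" in species_table:
                predictors.append("pla")
            screen = _pgls.screen_predictors(
                species_table, "percent_int", predictors, tree, models=config.models
            )
            report["pgls_screen"] = screen.to_dict(orient="records")
            screen.to_csv(out_dir / "pgls_screen.tsv", sep="\t", index=False)
            canonical = [
                "corolla_tube_length",
                "stigma_height",
                "upper_lip_length",
                "lower_lip_length",
            ]
            sel = screen[screen["selected"]].set_index("predictor")
            passed = [t for t in canonical if t in sel.index and sel.loc[t, "p"] < 0.05]
            log.info("PGLS screen: module traits passing at 0.05: %s", passed)
            report["pgls_passed_traits"] = passed

        if "psem" in config.stages:
            stage = "psem"
            if "pla" not in species_table:
                raise ValidationError("psem stage requires the pla stage")
            data = species_table.rename(
                columns={
                    "pla": "PLa",
                    "corolla_tube_length": "tube",
                    "stigma_height": "stigma",
                    "upper_lip_length": "upper",
                    "lower_lip_length": "lower",
                }
            )
            if config.psem_family_file:
                family = _psem.load_model_family(config.psem_family_file)
            else:
                family = _psem.enumerate_candidate_models()
            log.info("PSEM candidate family size: %d", len(family))
            fits = [
                _psem.fit_psem(m, data, tree, evolutionary_models=config.models)
                for m in family
            ]
            best, ranking = _psem.select_best(fits)
            report["psem"] = {
                "family_size": len(family),
                "ranking": ranking.to_dict(orient="records"),
                "best": None if best is None else best.as_dict(),
            }
            ranking.to_csv(out_dir / "psem_ranking.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report = _round_floats(report)
    (out_dir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    log.info("report written to %s", out_dir / "report.json")
    return report
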