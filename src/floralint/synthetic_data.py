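"""Synthetic honeysuckle-like datasets with known ground truth.

Generates everything the analysis chain consumes — an ultrametric
phylogeny, species-level trait means produced by an explicit causal
structure (composite proboscis length -> corolla tube, -> stigma height;
stigma height -> upper lip; correlated residuals tube~stigma and
upper~lower lip), individual flowers around those means, and pollinator
guilds with visitation records — so every downstream estimate can be
checked against the planted parameters.

The ``"lonicera-like"`` preset emulates the study system scale: 11 species,
8 floral traits, 30 flowers per species, 5 pollinator guilds whose mean
proboscis lengths span 2.45-41.15 mm, and within-species trait correlation
increasing with the assemblage proboscis length so that integration rises
along the pollinator gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .data_io import DEFAULT_TRAITS, ObservationTable, ProboscisTable, TraitTable
from .errors import ValidationError
from .trees import PhyloTree

__all__ = [
    "SyntheticTruth",
    "DatasetBundle",
    "simulate_tree",
    "simulate_species_means",
    "simulate_individuals",
    "simulate_observations",
    "make_dataset",
    "PRESETS",
]

#: default guild parameters: mean proboscis length (mm) and its sd
DEFAULT_GUILDS = {
    "small_carpenter_bee": (2.45, 0.12),
    "honeybee": (5.60, 0.28),
    "leafcutter_bee": (7.40, 0.37),
    "bumblebee": (9.80, 0.49),
    "hawkmoth": (41.15, 2.06),
}


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic dataset."""

    seed: int
    n_tips: int = 11
    # structural path coefficients (mm per mm)
    b_tube: float = 0.207  # PLa -> corolla tube length
    b_stigma: float = 1.765  # PLa -> stigma height
    b_upper: float = 0.232  # stigma height -> upper lip length
    b_lower_on_upper: float = 0.0  # optional direct upper -> lower path
    # residual correlations
    rho_tube_stigma: float = 0.7
    rho_upper_lower: float = 0.7
    # phylogenetic signal of the structural residuals
    lambda_true: float = 1.0
    # intercepts and residual standard deviations (mm)
    intercepts: dict = field(
        default_factory=lambda: {"tube": 5.0, "stigma": 5.0, "upper": 5.0, "lower": 10.0}
    )
    resid_sd: dict = field(
        default_factory=lambda: {"tube": 1.5, "stigma": 3.0, "upper": 2.0, "lower": 3.0}
    )
    # assemblage proboscis range the exp-BM predictor is rescaled to (mm)
    pla_range: tuple[float, float] = (2.45, 41.15)
    # within-species flower model
    cv: float = 0.08
    within_correlation: tuple[float, float] = (0.3, 0.62)  # equicorrelation gradient
    n_per_species: int = 30
    # pollinator observation model
    guilds: dict = field(default_factory=lambda: dict(DEFAULT_GUILDS))
    visit_rate: float = 0.5  # expected visits per flower per period, all guilds
    n_periods: int = 30
    n_specimens: int = 20
    match_bandwidth: float = 0.5  # log-scale proboscis/PLa matching kernel width

    def as_dict(self) -> dict:
        d = asdict(self)
        d["guilds"] = {k: list(v) for k, v in self.guilds.items()}
        d["pla_range"] = list(self.pla_range)
        d["within_correlation"] = list(self.within_correlation)
        return d


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to unit root-to-tip depth.

    Lineages split at unit rate, a uniformly chosen lineage splitting at
    each event; after the last split an extra exponential waiting time is
    appended so every terminal branch has positive length.  The tree is
    ultrametric by construction and deterministic under the seed.  Tips are
    labelled ``sp01 ... spNN``.
    """
    if n_tips < 3:
        raise ValidationError(f"need at least 3 tips, got {n_tips}")
    rng = np.random.default_rng(int(seed))
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        parent.edge.length = t - parent.birth_time if parent.parent_node else None
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / n_tips)  # tail: all tips sampled at time t
    for i, leaf in enumerate(active):
        leaf.edge.length = t - leaf.birth_time
        leaf.taxon = taxon_ns.new_taxon(f"sp{i + 1:02d}")
    # rescale crown depth (root split to tips) to one
    depth = t - tree.seed_node.split_time
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return PhyloTree(tree)


def _bm_sample(chol_c: np.ndarray, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    z = rng.standard_normal((chol_c.shape[0], size))
    return chol_c @ z


def simulate_species_means(
    truth: SyntheticTruth, tree: PhyloTree, seed: int | None = None
) -> pd.DataFrame:
    """Species-level trait means generated by the planted causal structure.

    The composite proboscis predictor is exp(Brownian motion) min-max
    rescaled to ``truth.pla_range`` (so the preset spans the full guild
    range).  Structural residuals are Brownian on the tree, transformed by
    ``lambda_true`` and correlated across equations (tube~stigma,
    upper~lower); traits follow the structural equations.  The four traits
    outside the causal core evolve as independent lognormal Brownian
    motions.  Trait means are floored at 0.5 mm (flowers cannot have
    negative parts); floor events are counted in the ``attrs``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    tips = tree.tip_labels
    n = len(tips)
    C = tree.bm_covariance(tips)
    Lc = cholesky(C, lower=True)

    z = _bm_sample(Lc, rng).ravel()
    lo, hi = truth.pla_range
    if z.max() == z.min():
        raise ValidationError("degenerate Brownian draw; increase tip count")
    zs = (z - z.min()) / (z.max() - z.min())
    pla = np.exp(np.log(lo) + zs * (np.log(hi) - np.log(lo)))

    # correlated structural residuals with phylogenetic signal lambda_true
    lam = truth.lambda_true
    C_lam = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    Ll = cholesky(C_lam, lower=True)
    r1, r2 = truth.rho_tube_stigma, truth.rho_upper_lower
    R_e = np.array(
        [
            [1.0, r1, 0.0, 0.0],
            [r1, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, r2],
            [0.0, 0.0, r2, 1.0],
        ]
    )
    try:
        Lr = cholesky(R_e, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"residual correlation matrix not positive-definite: {exc}")
    E = Ll @ rng.standard_normal((n, 4)) @ Lr.T
    sd = truth.resid_sd
    e_tube = E[:, 0] * sd["tube"]
    e_stigma = E[:, 1] * sd["stigma"]
    e_upper = E[:, 2] * sd["upper"]
    e_lower = E[:, 3] * sd["lower"]

    a = truth.intercepts
    tube = a["tube"] + truth.b_tube * pla + e_tube
    stigma = a["stigma"] + truth.b_stigma * pla + e_stigma
    upper = a["upper"] + truth.b_upper * stigma + e_upper
    lower = a["lower"] + truth.b_lower_on_upper * upper + e_lower

    # traits outside the causal core: independent lognormal Brownian motion
    throat = 2.8 * np.exp(0.25 * _bm_sample(Lc, rng).ravel())
    anther = 8.0 * np.exp(0.35 * _bm_sample(Lc, rng).ravel())
    upper_w = 3.3 * np.exp(0.20 * _bm_sample(Lc, rng).ravel())
    lower_w = 3.4 * np.exp(0.20 * _bm_sample(Lc, rng).ravel())

    frame = pd.DataFrame(
        {
            "pla_true": pla,
            "corolla_tube_length": tube,
            "throat_diameter": throat,
            "anther_height": anther,
            "stigma_height": stigma,
            "upper_lip_length": upper,
            "upper_lip_width": upper_w,
            "lower_lip_length": lower,
            "lower_lip_width": lower_w,
        },
        index=pd.Index(tips, name="species_id"),
    )
    floored = int((frame[list(DEFAULT_TRAITS)] < 0.5).to_numpy().sum())
    frame[list(DEFAULT_TRAITS)] = frame[list(DEFAULT_TRAITS)].clip(lower=0.5)
    frame.attrs["n_floored"] = floored
    return frame


#: species-means column -> causal-model variable name
CAUSAL_COLUMNS = {
    "pla_true": "PLa",
    "corolla_tube_length": "tube",
    "stigma_height": "stigma",
    "upper_lip_length": "upper",
    "lower_lip_length": "lower",
}


def causal_frame(species_means: pd.DataFrame) -> pd.DataFrame:
    """Project species means onto the causal model's variable names."""
    return species_means[list(CAUSAL_COLUMNS)].rename(columns=CAUSAL_COLUMNS)


def _equicorrelation(t: int, r: float) -> np.ndarray:
    R = np.full((t, t), r)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_individuals(
    species_means: pd.DataFrame,
    correlation,
    cv: float,
    n_per_species: int = 30,
    seed: int = 0,
) -> TraitTable:
    """Individual flowers around the species means.

    Per species, ``n_per_species`` multivariate-normal draws with mean
    equal to the species trait means, per-trait sd ``cv * mean`` and the
    given trait correlation matrix (either one matrix for all species or a
    mapping species -> matrix).  Rows containing a non-positive value are
    redrawn; the redraw count is stored in ``frame.attrs['n_redrawn']``.
    """
    if cv <= 0:
        raise ValidationError(f"coefficient of variation must be > 0, got {cv}")
    rng = np.random.default_rng(seed)
    rows = []
    n_redrawn = 0
    traits = list(DEFAULT_TRAITS)
    for sp in species_means.index:
        m = species_means.loc[sp, traits].to_numpy(float)
        R = correlation[sp] if isinstance(correlation, dict) else correlation
        R = np.asarray(R, float)
        D = np.diag(cv * m)
        cov = D @ R @ D
        try:
            L = cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"within-species covariance for {sp} not PD: {exc}")
        got = 0
        while got < n_per_species:
            draw = m + L @ rng.standard_normal(len(traits))
            if np.all(draw > 0):
                got += 1
                rows.append({"species_id": sp, "individual_id": f"{sp}_f{got:03d}",
                             **dict(zip(traits, draw))})
            else:
                n_redrawn += 1
    table = TraitTable(pd.DataFrame(rows))
    table.frame.attrs["n_redrawn"] = n_redrawn
    return table


def simulate_observations(
    truth: SyntheticTruth,
    species_means: pd.DataFrame,
    n_periods: int = 30,
    seed: int = 0,
) -> tuple[ObservationTable, ProboscisTable]:
    """Visitation records and proboscis specimens for every species.

    Guild visitation intensity for a species is proportional to a
    log-scale Gaussian matching kernel between the guild's mean proboscis
    length and the species' planted assemblage value, scaled so the total
    expected rate is ``truth.visit_rate`` visits per flower per period.
    Visits are Poisson given the number of open flowers (drawn uniformly
    from 3-12 per period); proboscis specimens are normal, truncated
    positive, ``truth.n_specimens`` per guild.
    """
    rng = np.random.default_rng(seed)
    guild_names = sorted(truth.guilds)
    pl_means = np.array([truth.guilds[g][0] for g in guild_names])
    obs_rows = []
    for sp in species_means.index:
        target = float(species_means.loc[sp, "pla_true"])
        w = np.exp(
            -((np.log(pl_means) - np.log(target)) ** 2)
            / (2.0 * truth.match_bandwidth**2)
        )
        if w.sum() == 0:
            raise ValidationError(f"all-zero visitation intensities for {sp}")
        intensity = truth.visit_rate * w / w.sum()
        for period in range(1, n_periods + 1):
            open_flowers = int(rng.integers(3, 13))
            for g, lam in zip(guild_names, intensity):
                visits = int(rng.poisson(lam * open_flowers))
                obs_rows.append(
                    {
                        "species_id": sp,
                        "guild_id": g,
                        "period_id": f"p{period:02d}",
                        "visits": visits,
                        "open_flowers": open_flowers,
                    }
                )
    prob_rows = []
    for g in guild_names:
        mean, sd = truth.guilds[g]
        got = 0
        while got < truth.n_specimens:
            x = float(rng.normal(mean, sd))
            if x > 0:
                got += 1
                prob_rows.append(
                    {"guild_id": g, "specimen_id": f"{g}_{got:03d}", "proboscis_length": x}
                )
    return ObservationTable(pd.DataFrame(obs_rows)), ProboscisTable(pd.DataFrame(prob_rows))


@dataclass
class DatasetBundle:
    """A complete synthetic dataset plus its ground truth."""

    tree: PhyloTree
    species_means: pd.DataFrame
    traits: TraitTable
    observations: ObservationTable
    proboscis: ProboscisTable
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        self.traits.write(out / "traits.csv")
        self.observations.write(out / "observations.csv")
        self.proboscis.write(out / "proboscis.csv")
        self.species_means.round(10).to_csv(out / "species_means.csv")
        (out / "truth.json").write_text(json.dumps(self.truth.as_dict(), sort_keys=True, indent=1))


PRESETS = ("lonicera-like",)


def within_species_correlations(
    truth: SyntheticTruth, species_means: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Equicorrelation level per species, increasing with the planted PLa.

    Species visited by longer-tongued assemblages receive more strongly
    correlated flowers, so the integration index rises along the pollinator
    gradient — the qualitative pattern the analyses are meant to detect.
    """
    r_lo, r_hi = truth.within_correlation
    pla = species_means["pla_true"]
    s = (np.log(pla) - np.log(pla.min())) / (np.log(pla.max()) - np.log(pla.min()))
    t = len(DEFAULT_TRAITS)
    return {
        sp: _equicorrelation(t, float(r_lo + s.loc[sp] * (r_hi - r_lo)))
        for sp in species_means.index
    }


def make_dataset(preset: str = "lonicera-like", seed: int = 0, **overrides) -> DatasetBundle:
    """Generate the full synthetic bundle for a named preset.

    ``"lonicera-like"``: 11 species on a unit-depth Yule tree, 8 traits,
    30 flowers per species, 5 guilds spanning 2.45-41.15 mm proboscis
    length, 30 observation periods, planted paths PLa->tube (0.207),
    PLa->stigma (1.765) and stigma->upper (0.232) with residual
    correlations 0.7.  Keyword overrides replace individual truth fields.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; available: {PRESETS}")
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    truth = SyntheticTruth(seed=seed, **overrides)
    tree = simulate_tree(truth.n_tips, seed=sub[0])
    means = simulate_species_means(truth, tree, seed=sub[1])
    corrs = within_species_correlations(truth, means)
    traits = simulate_individuals(
        means, corrs, truth.cv, n_per_species=truth.n_per_species, seed=sub[2]
    )
    obs, prob = simulate_observations(truth, means, n_periods=truth.n_periods, seed=sub[3])
    return DatasetBundle(
        tree=tree,
        species_means=means,
        traits=traits,
        observations=obs,
        proboscis=prob,
        truth=truth,
    )
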