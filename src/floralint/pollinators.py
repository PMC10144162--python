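"""Guild visitation rates and the composite proboscis length of an assemblage.

A plant species is visited by several pollinator guilds (bumblebees,
honeybees, hawkmoths, ...), each with its own mean proboscis length
``PL_i`` and visitation rate ``VF_i`` (visits per open flower per
observation period).  The assemblage-level composite proboscis length is
the visitation-weighted mean

    PLa = sum_i PL_i * VF_i / VF_n,      VF_n = sum_i VF_i,

so it always lies between the shortest and longest guild mean and is
invariant to rescaling all visitation rates by a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GuildSummary",
    "AssemblageSummary",
    "visitation_rates",
    "guild_proboscis_means",
    "composite_proboscis_length",
    "species_assemblages",
]


@dataclass
class GuildSummary:
    guild_id: str
    proboscis_mean: float  # PL_i, mm
    n_specimens: int
    visitation_rate: float  # VF_i, visits per flower per period

    def __post_init__(self):
        if self.proboscis_mean <= 0:
            raise ValidationError(f"guild {self.guild_id}: proboscis mean must be > 0")
        if self.visitation_rate < 0:
            raise ValidationError(f"guild {self.guild_id}: visitation rate must be >= 0")
        if self.n_specimens < 1:
            raise ValidationError(f"guild {self.guild_id}: needs >= 1 specimen")


@dataclass
class AssemblageSummary:
    species_id: str
    n_guilds: int
    vf_total: float  # VF_n
    pla: float  # composite proboscis length, mm


def visitation_rates(
    obs, species_id: str, *, aggregation: str = "mean_of_periods"
) -> pd.Series:
    """Per-guild visitation rates VF_i for one plant species.

    The per-period rate of a guild is ``visits / open_flowers``.  With the
    default ``aggregation="mean_of_periods"`` VF_i is the mean of these
    rates over every observation period recorded for the species, with
    periods in which the guild made no visits contributing zero.  The
    alternative ``"pooled"`` divides total visits by total flower-periods.
    """
    frame = obs.frame
    sub = frame[frame["species_id"] == species_id]
    if sub.empty:
        raise ValidationError(f"no observations for species {species_id!r}")
    periods = sorted(sub["period_id"].astype(str).unique())
    guilds = sorted(sub["guild_id"].astype(str).unique())
    if aggregation == "mean_of_periods":
        # complete guild x period grid; absent combinations are zero visits
        rate = sub.assign(rate=sub["visits"] / sub["open_flowers"])
        grid = rate.pivot_table(
            index="guild_id", columns="period_id", values="rate", aggfunc="sum", fill_value=0.0
        ).reindex(index=guilds, columns=periods, fill_value=0.0)
        vf = grid.mean(axis=1)
    elif aggregation == "pooled":
        tot_flowers = float(
            sub.drop_duplicates(["period_id"])["open_flowers"].sum()
        )
        vf = sub.groupby("guild_id")["visits"].sum() / tot_flowers
        vf = vf.reindex(guilds, fill_value=0.0)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    vf.name = "visitation_rate"
    return vf.astype(float)


def guild_proboscis_means(prob, guilds=None) -> pd.DataFrame:
    """Arithmetic mean proboscis length (mm) and specimen count per guild."""
    frame = prob.frame
    summary = frame.groupby("guild_id")["proboscis_length"].agg(["mean", "count"])
    summary.columns = ["proboscis_mean", "n_specimens"]
    if guilds is not None:
        missing = sorted(set(guilds) - set(summary.index))
        if missing:
            raise ValidationError(f"guilds with no proboscis specimens: {missing}")
        summary = summary.loc[list(guilds)]
    return summary


def composite_proboscis_length(
    guilds: list[GuildSummary], species_id: str = ""
) -> AssemblageSummary:
    """Visitation-weighted composite proboscis length of an assemblage."""
    if not guilds:
        raise ValidationError("assemblage must contain at least one guild")
    pl = np.array([g.proboscis_mean for g in guilds])
    vf = np.array([g.visitation_rate for g in guilds])
    vf_total = float(vf.sum())
    if vf_total == 0:
        raise ValidationError(
            f"assemblage for {species_id!r} has zero total visitation; PLa undefined"
        )
    pla = float((pl * vf).sum() / vf_total)
    return AssemblageSummary(
        species_id=species_id, n_guilds=len(guilds), vf_total=vf_total, pla=pla
    )


def species_assemblages(
    obs, prob, *, aggregation: str = "mean_of_periods"
) -> dict[str, AssemblageSummary]:
    """Composite proboscis length for every species in an observation table."""
    pl_table = guild_proboscis_means(prob)
    out = {}
    for sp in obs.species():
        vf = visitation_rates(obs, sp, aggregation=aggregation)
        missing = sorted(set(vf.index) - set(pl_table.index))
        if missing:
            raise ValidationError(
                f"species {sp!r}: observed guilds without proboscis data: {missing}"
            )
        summaries = [
            GuildSummary(
                guild_id=g,
                proboscis_mean=float(pl_table.loc[g, "proboscis_mean"]),
                n_specimens=int(pl_table.loc[g, "n_specimens"]),
                visitation_rate=float(vf.loc[g]),
            )
            for g in vf.index
        ]
        out[sp] = composite_proboscis_length(summaries, species_id=sp)
    return out
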