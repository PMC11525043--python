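"""Domain containers and preprocessing for site-by-species community data.

Two guilds are analysed throughout: herbaceous flowering plants (percent
cover per site) and day-active butterflies (transect counts pooled within a
survey season).  A third, derived abundance type — flower availability
(mean flowering units per species and site) — shares the same container.

Orientation convention: sites are rows, species are columns, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALB_SCALE",
    "SCH_SCALE",
    "OccurrenceData",
    "InteractionMatrix",
    "pool_butterfly_surveys",
    "binarize",
    "log1p_flowers",
    "filter_to_shared_species",
    "merge_duplicate_plants",
]

#: Interaction-strength coding used for the six-level literature scale
#: (0 = no recorded flower visit ... 1 = nectar plant of paramount importance).
ALB_SCALE = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
#: Reduced four-level coding used where intermediate levels were not scored.
SCH_SCALE = (0.0, 0.2, 0.6, 1.0)

PLANT = "plant"
BUTTERFLY = "butterfly"
FLOWER = "flower"
_GUILDS = frozenset({PLANT, BUTTERFLY, FLOWER})


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes}")
    return ids


@dataclass
class OccurrenceData:
    """Site-by-species abundance matrix for one guild.

    Parameters
    ----------
    sites : ordered site identifiers (rows).
    species : ordered species identifiers (columns).
    guild : one of ``{"plant", "butterfly", "flower"}``.
    abundance : non-negative real matrix, shape ``(len(sites), len(species))``.
        Percent cover for plants, mean pooled transect counts for
        butterflies, mean flowering units for flower availability.

    The binary ``presence`` view is derived strictly as ``abundance > 0``;
    no minimum-abundance threshold is applied.
    """

    sites: list[str]
    species: list[str]
    guild: str
    abundance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sites = _check_unique(self.sites, "site")
        self.species = _check_unique(self.species, "species")
        if self.guild not in _GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}; expected one of {sorted(_GUILDS)}")
        a = np.asarray(self.abundance, dtype=float)
        if a.shape != (len(self.sites), len(self.species)):
            raise ValueError(
                f"abundance shape {a.shape} does not match "
                f"({len(self.sites)} sites, {len(self.species)} species)"
            )
        if a.size and not np.all(np.isfinite(a)):
            raise ValueError("abundance contains non-finite values")
        if a.size and (a < 0).any():
            raise ValueError("abundance contains negative values")
        self.abundance = a

    @property
    def presence(self) -> np.ndarray:
        """Binary sites x species matrix, 1 exactly where abundance > 0."""
        return (self.abundance > 0).astype(np.uint8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def occupancy(self) -> np.ndarray:
        """Per-species occupancy counts n_i (column sums of presence)."""
        return self.presence.sum(axis=0).astype(int)

    @property
    def total_presences(self) -> int:
        """Total number of presences L (grand sum of the binary matrix)."""
        return int(self.presence.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=pd.Index(self.sites, name="site"),
                            columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, guild: str) -> "OccurrenceData":
        return cls(sites=list(df.index.astype(str)), species=list(df.columns.astype(str)),
                   guild=guild, abundance=df.to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        # repr gives the shortest exact decimal, so read-back is lossless
        self.to_frame().to_csv(path, float_format=lambda x: repr(float(x)))

    @classmethod
    def read_csv(cls, path, guild: str) -> "OccurrenceData":
        return cls.from_frame(pd.read_csv(path, index_col=0, float_precision="round_trip"), guild)

    def subset(self, sites: Sequence[str] | None = None,
               species: Sequence[str] | None = None) -> "OccurrenceData":
        """Return a copy restricted (and reordered) to the given ids."""
        sites = list(self.sites) if sites is None else [str(s) for s in sites]
        species = list(self.species) if species is None else [str(s) for s in species]
        ri = [self.sites.index(s) for s in sites]
        ci = [self.species.index(s) for s in species]
        return OccurrenceData(sites=sites, species=species, guild=self.guild,
                              abundance=self.abundance[np.ix_(ri, ci)] if ri and ci
                              else np.zeros((len(ri), len(ci))))


@dataclass
class InteractionMatrix:
    """Literature-coded plants x butterflies interaction strengths.

    Strengths come from a declared ordinal scale (e.g. the six-level
    ``ALB_SCALE`` or four-level ``SCH_SCALE``); 0 means no recorded
    interaction.  Binarized links (strength > 0) define the known-link set
    used as ground truth in the accuracy analysis.
    """

    plants: list[str]
    butterflies: list[str]
    strength: np.ndarray = field(repr=False)
    scale: tuple[float, ...] = ALB_SCALE

    def __post_init__(self) -> None:
        self.plants = _check_unique(self.plants, "plant")
        self.butterflies = _check_unique(self.butterflies, "butterfly")
        s = np.asarray(self.strength, dtype=float)
        if s.shape != (len(self.plants), len(self.butterflies)):
            raise ValueError(
                f"strength shape {s.shape} does not match "
                f"({len(self.plants)} plants, {len(self.butterflies)} butterflies)"
            )
        self.scale = tuple(sorted(float(v) for v in self.scale))
        if s.size:
            allowed = np.asarray(self.scale)
            ok = np.isclose(s[:, :, None], allowed[None, None, :]).any(axis=2)
            if not ok.all():
                bad = sorted(set(np.round(s[~ok], 6)))
                raise ValueError(f"strength values {bad} not in declared scale {self.scale}")
        self.strength = s

    @property
    def links(self) -> np.ndarray:
        """Binary known-link matrix (strength > 0)."""
        return (self.strength > 0).astype(np.uint8)

    @property
    def n_links(self) -> int:
        return int(self.links.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.strength, index=pd.Index(self.plants, name="plant"),
                            columns=self.butterflies)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: tuple[float, ...] = ALB_SCALE) -> "InteractionMatrix":
        return cls(plants=list(df.index.astype(str)), butterflies=list(df.columns.astype(str)),
                   strength=df.to_numpy(dtype=float), scale=scale)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format=lambda x: repr(float(x)))

    @classmethod
    def read_csv(cls, path, scale: tuple[float, ...] = ALB_SCALE) -> "InteractionMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0, float_precision="round_trip"), scale)

    def to_long(self) -> pd.DataFrame:
        """Long-format (plant, butterfly, strength) list including zeros."""
        return (self.to_frame().reset_index()
                .melt(id_vars="plant", var_name="butterfly", value_name="strength"))

    @classmethod
    def from_long(cls, df: pd.DataFrame, scale: tuple[float, ...] = ALB_SCALE,
                  plants: Sequence[str] | None = None,
                  butterflies: Sequence[str] | None = None) -> "InteractionMatrix":
        """Pivot a long (plant, butterfly, strength) list; missing pairs get 0."""
        wide = df.pivot_table(index="plant", columns="butterfly", values="strength",
                              aggfunc="max", fill_value=0.0)
        if plants is not None:
            wide = wide.reindex(index=[str(p) for p in plants], fill_value=0.0)
        if butterflies is not None:
            wide = wide.reindex(columns=[str(b) for b in butterflies], fill_value=0.0)
        return cls.from_frame(wide, scale)

    def subset(self, plants: Sequence[str], butterflies: Sequence[str]) -> "InteractionMatrix":
        ri = [self.plants.index(p) for p in plants]
        ci = [self.butterflies.index(b) for b in butterflies]
        return InteractionMatrix(plants=list(plants), butterflies=list(butterflies),
                                 strength=self.strength[np.ix_(ri, ci)], scale=self.scale)

    def align_to(self, plants: Sequence[str], butterflies: Sequence[str]) -> "InteractionMatrix":
        """Reindex to the given species lists; unknown species get strength 0.

        Species observed in the field but absent from the literature
        compilation are kept as all-zero rows/columns so that every
        plant x butterfly pair of the occurrence data counts as a potential
        interaction.
        """
        df = self.to_frame().reindex(index=[str(p) for p in plants],
                                     columns=[str(b) for b in butterflies],
                                     fill_value=0.0)
        return InteractionMatrix.from_frame(df, self.scale)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def pool_butterfly_surveys(per_interval_counts: np.ndarray,
                           sites: Sequence[str],
                           species: Sequence[str]) -> OccurrenceData:
    """Pool repeated transect surveys into one seasonal abundance per site.

    ``per_interval_counts`` has shape (n_surveys, n_intervals, n_sites,
    n_species).  Counts are first summed over the transect intervals within
    each survey (total abundance per species, site and survey) and then
    averaged across surveys (total abundance for the season per species and
    site).

    Raises
    ------
    ValueError
        on negative counts or an empty survey/interval axis.
    """
    c = np.asarray(per_interval_counts, dtype=float)
    if c.ndim != 4:
        raise ValueError("expected a 4-D array (surveys, intervals, sites, species)")
    if c.shape[0] < 1 or c.shape[1] < 1:
        raise ValueError("need at least one survey and one interval")
    if c.shape[2:] != (len(sites), len(species)):
        raise ValueError("trailing dimensions must match (sites, species)")
    if c.size and (c < 0).any():
        raise ValueError("negative counts are not valid abundances")
    pooled = c.sum(axis=1).mean(axis=0)
    return OccurrenceData(sites=list(sites), species=list(species),
                          guild=BUTTERFLY, abundance=pooled)


def binarize(data: OccurrenceData) -> np.ndarray:
    """Boolean (0/1) sites x species matrix; column sums are occupancies n_i."""
    return data.presence


def log1p_flowers(flowers: OccurrenceData) -> OccurrenceData:
    """log(x+1)-transform flower counts to tame their dynamic range.

    The map is monotone and fixes 0, so the presence pattern is unchanged.
    """
    if flowers.guild != FLOWER:
        raise ValueError(f"expected flower-availability data, got guild {flowers.guild!r}")
    return replace(flowers, abundance=np.log1p(flowers.abundance))


def average_flower_surveys(per_date_units: np.ndarray, sites: Sequence[str],
                           species: Sequence[str]) -> OccurrenceData:
    """Average flowering units per species and site across sampling dates.

    ``per_date_units`` has shape (n_dates, n_sites, n_species).
    """
    u = np.asarray(per_date_units, dtype=float)
    if u.ndim != 3 or u.shape[0] < 1:
        raise ValueError("expected a non-empty 3-D array (dates, sites, species)")
    if u.size and (u < 0).any():
        raise ValueError("negative flowering-unit counts")
    return OccurrenceData(sites=list(sites), species=list(species),
                          guild=FLOWER, abundance=u.mean(axis=0))


def filter_to_shared_species(occ_plants: OccurrenceData,
                             occ_butterflies: OccurrenceData,
                             interactions: InteractionMatrix,
                             ) -> tuple[OccurrenceData, OccurrenceData, InteractionMatrix]:
    """Restrict all three objects to the species shared with the occurrence data
    and to sites sampled for both guilds.

    The interaction matrix is filtered to species present in the occurrence
    data; order follows the occurrence data.  Sites are restricted to the
    intersection of the two occurrence site lists (removing sites where one
    guild was not sampled).  Species in the occurrence data but absent from
    the interaction compilation are kept with strength 0 for all partners.
    """
    shared_sites = [s for s in occ_plants.sites if s in set(occ_butterflies.sites)]
    if not shared_sites:
        raise ValueError("no sites are shared between the two occurrence datasets")
    inter_p = set(interactions.plants) & set(occ_plants.species)
    inter_b = set(interactions.butterflies) & set(occ_butterflies.species)
    if not inter_p:
        raise ValueError("empty species intersection for guild 'plant'")
    if not inter_b:
        raise ValueError("empty species intersection for guild 'butterfly'")
    plants = occ_plants.subset(sites=shared_sites)
    butterflies = occ_butterflies.subset(sites=shared_sites)
    truth = interactions.align_to(plants.species, butterflies.species)
    return plants, butterflies, truth


def merge_duplicate_plants(long_interactions: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (plant, butterfly) records keeping the highest strength.

    Utility for literature compilations where one taxon appears under
    several names or sub-taxa (aggregates, subspecies): records are merged
    onto the shared name and, where a butterfly interacts with more than one
    of them, the highest coded interaction strength is retained.
    """
    return (long_interactions.groupby(["plant", "butterfly"], as_index=False)["strength"]
            .max())
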