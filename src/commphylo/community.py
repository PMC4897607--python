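"""Plot-by-species community data with succession stages and life forms.

The canonical on-disk representation is three CSV tables: a long-format
community table (plot, species, abundance = relative coverage), plot metadata
(plot, stage 1-6, plot_size) and species metadata (species, life_form
woody|herbaceous).  In memory the data live in a wide pandas DataFrame
(plots x species) inside :class:`CommunityMatrix`, renormalized so each
plot's coverages sum to 1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STAGES = frozenset(range(1, 7))
VALID_LIFE_FORMS = frozenset({"woody", "herbaceous"})


class CommunityValidationError(ValueError):
    """Raised when community tables violate an invariant."""


class CommunityMatrix:
    """Validated plot x species abundance matrix with plot/species metadata.

    Parameters
    ----------
    wide:
        DataFrame indexed by plot id with species ids as columns; values are
        nonnegative relative coverages.
    plot_meta:
        DataFrame indexed by plot id with columns ``stage`` (int, 1-6) and
        optionally ``plot_size`` (free-text label).
    species_meta:
        DataFrame indexed by species id with column ``life_form``
        (``woody`` or ``herbaceous``).
    renormalize:
        Rescale each plot row to sum to 1 (the convention assumed by the
        abundance-weighted metrics).  Ratios between species within a plot
        are unchanged.
    """

    def __init__(self, wide: pd.DataFrame, plot_meta: pd.DataFrame,
                 species_meta: pd.DataFrame, renormalize: bool = True):
        wide = wide.astype(float).copy()
        if wide.index.has_duplicates or wide.columns.has_duplicates:
            raise CommunityValidationError("duplicate plot or species ids")
        if (wide.values < 0).any():
            raise CommunityValidationError("negative abundances")

        missing_plots = wide.index.difference(plot_meta.index)
        if len(missing_plots):
            raise CommunityValidationError(
                f"plots missing from plot metadata: {sorted(missing_plots)}")
        missing_sp = wide.columns.difference(species_meta.index)
        if len(missing_sp):
            raise CommunityValidationError(
                f"species missing from species metadata: {sorted(missing_sp)}")

        plot_meta = plot_meta.loc[wide.index].copy()
        # keep every species described in the metadata: the regional pool may
        # include species that happen not to occur in any surveyed plot
        extra_sp = species_meta.index.difference(wide.columns)
        if len(extra_sp):
            wide = wide.reindex(columns=list(wide.columns) + list(extra_sp), fill_value=0.0)
        species_meta = species_meta.loc[wide.columns].copy()

        stages = pd.to_numeric(plot_meta["stage"], errors="coerce")
        if stages.isna().any() or not set(stages.astype(int)) <= VALID_STAGES:
            bad = plot_meta.loc[~stages.isin(list(VALID_STAGES)), "stage"]
            raise CommunityValidationError(f"invalid succession stages: {bad.to_dict()}")
        plot_meta["stage"] = stages.astype(int)

        bad_lf = set(species_meta["life_form"]) - VALID_LIFE_FORMS
        if bad_lf:
            raise CommunityValidationError(f"invalid life forms: {sorted(bad_lf)}")

        rowsum = wide.sum(axis=1)
        empty = rowsum[rowsum <= 0]
        if len(empty):
            raise CommunityValidationError(
                f"plots with zero total abundance (richness >= 1 required): "
                f"{sorted(empty.index)}")
        if renormalize:
            wide = wide.div(rowsum, axis=0)

        self.wide = wide
        self.plot_meta = plot_meta
        self.species_meta = species_meta

    # -- accessors ---------------------------------------------------------

    @property
    def plots(self) -> pd.Index:
        return self.wide.index

    @property
    def species(self) -> pd.Index:
        return self.wide.columns

    @property
    def abundance(self) -> np.ndarray:
        return self.wide.values

    @property
    def presence(self) -> np.ndarray:
        return (self.wide.values > 0).astype(np.uint8)

    @property
    def stages(self) -> pd.Series:
        return self.plot_meta["stage"]

    @property
    def life_forms(self) -> pd.Series:
        return self.species_meta["life_form"]

    @property
    def richness(self) -> pd.Series:
        return (self.wide > 0).sum(axis=1)

    def species_set(self, plot) -> set:
        row = self.wide.loc[plot]
        return set(row.index[row > 0])

    def occurring_species(self) -> pd.Index:
        return self.species[(self.wide > 0).any(axis=0)]

    def __repr__(self):
        return (f"CommunityMatrix({len(self.plots)} plots x {len(self.species)} species, "
                f"stages {sorted(self.stages.unique())})")

    # -- subsetting --------------------------------------------------------

    def subset(self, stage=None, life_form=None, renormalize: bool = True) -> "CommunityMatrix":
        """Restrict to one succession stage and/or one life form.

        Stages may be a single int or an iterable of ints.  Under a life-form
        filter, plots whose richness drops to zero are dropped (with a logged
        count) and, when ``renormalize`` is true, coverages are rescaled
        within the retained species so abundance weights are conditional on
        the life form.
        """
        wide = self.wide
        plot_meta = self.plot_meta
        species_meta = self.species_meta

        if stage is not None:
            stages = {int(stage)} if np.isscalar(stage) else {int(s) for s in stage}
            keep = plot_meta["stage"].isin(stages)
            if not keep.any():
                raise CommunityValidationError(f"no plots in stage(s) {sorted(stages)}")
            wide = wide.loc[keep]
            plot_meta = plot_meta.loc[keep]

        if life_form is not None:
            if life_form not in VALID_LIFE_FORMS:
                raise CommunityValidationError(f"unknown life form {life_form!r}")
            sp_keep = species_meta["life_form"] == life_form
            if not sp_keep.any():
                raise CommunityValidationError(f"no {life_form} species present")
            wide = wide.loc[:, sp_keep]
            species_meta = species_meta.loc[sp_keep]
            rowsum = wide.sum(axis=1)
            dropped = int((rowsum <= 0).sum())
            if dropped:
                logger.info("dropping %d plot(s) with no %s species", dropped, life_form)
            wide = wide.loc[rowsum > 0]
            plot_meta = plot_meta.loc[wide.index]
            if wide.empty:
                raise CommunityValidationError(
                    f"no plots retain any species under filter life_form={life_form!r}")

        return CommunityMatrix(wide, plot_meta, species_meta, renormalize=renormalize)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_long(cls, community: pd.DataFrame, plot_meta: pd.DataFrame,
                  species_meta: pd.DataFrame, renormalize: bool = True) -> "CommunityMatrix":
        required = {"plot", "species", "abundance"}
        if not required <= set(community.columns):
            raise CommunityValidationError(
                f"community table needs columns {sorted(required)}")
        if community.duplicated(["plot", "species"]).any():
            n = int(community.duplicated(["plot", "species"]).sum())
            logger.warning("summing %d duplicate (plot, species) rows", n)
        wide = (community.pivot_table(index="plot", columns="species",
                                      values="abundance", aggfunc="sum", fill_value=0.0))
        wide.index.name = None
        wide.columns.name = None
        return cls(wide, plot_meta, species_meta, renormalize=renormalize)

    @classmethod
    def read(cls, community_csv, plot_meta_csv, species_meta_csv,
             renormalize: bool = True) -> "CommunityMatrix":
        community = pd.read_csv(community_csv)
        plot_meta = pd.read_csv(plot_meta_csv).set_index("plot")
        species_meta = pd.read_csv(species_meta_csv).set_index("species")
        if (pd.to_numeric(community["abundance"], errors="coerce") < 0).any():
            raise CommunityValidationError("negative abundance in community table")
        return cls.from_long(community, plot_meta, species_meta, renormalize=renormalize)

    def to_long(self) -> pd.DataFrame:
        long = self.wide.stack().rename("abundance").reset_index()
        long.columns = ["plot", "species", "abundance"]
        return long[long["abundance"] > 0].reset_index(drop=True)

    def write(self, outdir, prefix: str = "") -> dict:
        """Write community/plot/species CSVs; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "community": outdir / f"{prefix}community.csv",
            "plots": outdir / f"{prefix}plots.csv",
            "species": outdir / f"{prefix}species.csv",
        }
        self.to_long().to_csv(paths["community"], index=False)
        self.plot_meta.rename_axis("plot").reset_index().to_csv(paths["plots"], index=False)
        self.species_meta.rename_axis("species").reset_index().to_csv(paths["species"], index=False)
        return paths

    def write_wide(self, path) -> None:
        self.wide.rename_axis("plot").to_csv(path)


def read_community(community_csv, plot_meta_csv, species_meta_csv,
                   renormalize: bool = True) -> CommunityMatrix:
    """Load and validate the three community CSV tables."""
    return CommunityMatrix.read(community_csv, plot_meta_csv, species_meta_csv,
                                renormalize=renormalize)
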