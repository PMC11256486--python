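"""Core data types and tab-delimited I/O for the TMT serum pipeline.

The pipeline's entry point is a PSM-level table in the style of a Proteome
Discoverer multi-consensus export: one row per peptide-spectrum match with
eleven raw reporter-ion intensities (TMT 11-plex channels 126..131C), an
isolation-interference percentage, a confidence rank and a protein-group
accession.  Everything downstream operates on pandas objects; a light
``FeatureMatrix`` wrapper carries the features x samples log2-ratio matrix
together with the feature -> protein-group mapping.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: TMT 11-plex reporter channels, in mass order.
CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131", "131C",
)

#: Canonical PSM-table column names (the writer's header line).
PSM_COLUMNS: tuple[str, ...] = (
    "plex", "peptide", "protein_groups", "interference", "rank", *CHANNELS
)

#: Dialect mapping canonical names to Proteome Discoverer-style headers.
#: PD export headers vary by version, so readers take a dialect map rather
#: than hard-coding these.
PD_DIALECT: dict[str, str] = {
    "plex": "File ID",
    "peptide": "Annotated Sequence",
    "protein_groups": "Master Protein Accessions",
    "interference": "Isolation Interference [%]",
    "rank": "Rank",
    **{ch: f"Abundance {ch}" for ch in CHANNELS},
}

GROUP_SEP = ";"  # accession separator inside the protein_groups column


class FormatError(ValueError):
    """A table does not conform to the expected layout."""


class ConfigurationError(ValueError):
    """Metadata / configuration inconsistent with the data."""


# ---------------------------------------------------------------------------
# PSM table
# ---------------------------------------------------------------------------

def read_psm_table(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited PSM table.

    Parameters
    ----------
    path : path-like or file-like
        Tab-separated UTF-8 file with one row per PSM.
    dialect : dict, optional
        Map from canonical column names (``plex``, ``peptide``,
        ``protein_groups``, ``interference``, ``rank`` and the eleven channel
        names) to the headers actually present in the file.  Defaults to the
        canonical names themselves; use :data:`PD_DIALECT` for Proteome
        Discoverer-style exports.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`PSM_COLUMNS`; missing intensity or interference cells
        are ``NaN`` (never silently zero), empty accessions are ``""``.
    """
    dialect = dict(dialect) if dialect else {c: c for c in PSM_COLUMNS}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [dialect.get(c, c) for c in PSM_COLUMNS
                    if dialect.get(c, c) not in raw.columns]
    if missing_cols:
        raise FormatError(
            f"PSM table is missing required column(s): {', '.join(missing_cols)} "
            f"(11 reporter channels {CHANNELS[0]}..{CHANNELS[-1]} are required)"
        )
    out = pd.DataFrame(index=raw.index)
    out["plex"] = raw[dialect.get("plex", "plex")].astype(str)
    out["peptide"] = raw[dialect.get("peptide", "peptide")].str.upper()
    out["protein_groups"] = raw[dialect.get("protein_groups", "protein_groups")]
    for col in ("interference", "rank", *CHANNELS):
        src = raw[dialect.get(col, col)]
        vals = pd.to_numeric(src.replace("", np.nan), errors="coerce")
        bad = vals.isna() & src.replace("", np.nan).notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(
                f"non-numeric value {src[bad.idxmax()]!r} in column "
                f"{dialect.get(col, col)!r} at line {line}"
            )
        out[col] = vals
    out["rank"] = out["rank"].astype("Int64")
    validate_psm_table(out)
    return out


def write_psm_table(psm: pd.DataFrame, path) -> None:
    """Write a PSM table with canonical headers (lossless round-trip)."""
    psm.to_csv(path, sep="\t", index=False, na_rep="")


def validate_psm_table(psm: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in psm.columns]
    if missing:
        raise FormatError(f"PSM table missing column(s): {', '.join(missing)}")
    interf = psm["interference"].dropna()
    if ((interf < 0) | (interf > 100)).any():
        raise FormatError("isolation interference outside [0, 100]")
    neg = psm[list(CHANNELS)].lt(0).any().any()
    if neg:
        raise FormatError("negative reporter intensities")


def split_groups(accessions: str) -> frozenset[str]:
    """Split a ';'-joined accession string into a set (empty string -> empty set)."""
    if not accessions:
        return frozenset()
    return frozenset(a.strip() for a in accessions.split(GROUP_SEP) if a.strip())


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS: tuple[str, ...] = (
    "sample_id", "plex", "channel", "role", "group", "centre",
    "sex", "age", "injury_level", "ais_grade", "storage_days",
)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing column(s): {', '.join(missing)}")
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    meta["storage_days"] = pd.to_numeric(meta["storage_days"], errors="coerce")
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_metadata(meta: pd.DataFrame) -> None:
    """Enforce the study-layout invariants.

    Exactly one reference-pool channel per plex (the pool is declared in the
    metadata, never assumed to sit in a fixed channel), unique sample ids,
    and a unique (plex, channel) slot per sample.
    """
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConfigurationError(f"duplicated sample_id {dup!r}")
    if meta.duplicated(["plex", "channel"]).any():
        raise ConfigurationError("duplicated (plex, channel) assignment")
    refs = meta[meta["role"] == "reference_pool"].groupby("plex").size()
    plexes = meta["plex"].unique()
    bad = [p for p in plexes if refs.get(p, 0) != 1]
    if bad:
        raise ConfigurationError(
            f"each plex needs exactly one reference_pool channel; offending plex(es): {bad}"
        )
    exp = meta[meta["role"] == "experimental"]
    if not exp["group"].isin(["NR", "SR"]).all():
        raise ConfigurationError("experimental samples must be labelled NR or SR")


def experimental_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Experimental rows, indexed by sample_id, in metadata order."""
    exp = meta[meta["role"] == "experimental"].copy()
    return exp.set_index("sample_id", drop=False)


def reference_channels(meta: pd.DataFrame) -> dict[str, str]:
    """Map plex -> reference-pool channel."""
    refs = meta[meta["role"] == "reference_pool"]
    return dict(zip(refs["plex"], refs["channel"]))


# ---------------------------------------------------------------------------
# Feature matrix (peptide- or protein-level)
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """A features x samples matrix on the log2-ratio scale.

    ``values`` holds one row per feature (peptide sequence or protein-group
    accession) and one column per experimental sample; ``NaN`` marks missing.
    ``groups`` maps each feature to its protein-group accession set.
    """

    values: pd.DataFrame
    groups: pd.Series  # feature -> frozenset of accessions

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise FormatError("duplicated feature ids")
        self.groups = self.groups.reindex(self.values.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def group_unique(self) -> pd.Series:
        """True where a feature maps to exactly one protein group."""
        return self.groups.map(lambda s: len(s) == 1 if s is not None else False)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.groups.copy())

    def select(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[mask], self.groups.loc[mask])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "protein_groups",
                   self.groups.map(lambda s: GROUP_SEP.join(sorted(s))))
        out.index.name = "feature"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        groups = df.pop("protein_groups").map(split_groups)
        values = df.apply(pd.to_numeric, errors="coerce")
        return cls(values, groups)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable thresholds of the analysis, serialisable to YAML.

    Defaults follow the published workflow: PSMs above 45 % isolation
    interference are dropped, peptides missing in more than ~36 % of either
    recovery group are removed, and significance uses p < 0.01 with a 1.8
    fold-change threshold for peptides, p < 0.05 / 1.6-fold / FDR 0.1 for
    proteins, where the fold-change threshold itself is recomputed from the
    data as 2^(1.47 x median SD).
    """

    interference_threshold: float = 45.0
    missing_fraction_threshold: float = 0.36
    ipca_components: int = 2
    ipca_tol: float = 1e-4
    ipca_max_iter: int = 200
    trim_fraction: float = 0.20
    fct_multiplier: float = 1.47
    peptide_alpha: float = 0.01
    protein_alpha: float = 0.05
    protein_fdr: float = 0.10
    enrichment_adjp: float = 0.30
    enrichment_min_matches: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.interference_threshold <= 100:
            raise ValueError("interference_threshold must be in [0, 100]")
        if not 0 <= self.missing_fraction_threshold <= 1:
            raise ValueError("missing_fraction_threshold must be in [0, 1]")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        for name in ("peptide_alpha", "protein_alpha", "protein_fdr",
                     "enrichment_adjp"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**data)
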