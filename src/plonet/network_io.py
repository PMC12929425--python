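"""Reading, validation and writing of interaction matrices and trait tables.

A plant-pollinator community is stored as a labelled non-negative weight
matrix: rows are plant species, columns are pollinator taxa, and each cell
holds the observed visit count (or visit frequency).  Trait tables carry one
row per plant species with categorical ploidy, mating-system and floral
restrictiveness values; covariate tables carry one row per network with
coordinates and bioclimatic variables.

All delimited text is UTF-8; the delimiter is auto-detected among comma, tab
and semicolon unless given explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("plonet")

PLOIDY_LEVELS = ("diploid", "polyploid", "unknown")
MATING_LEVELS = ("self_compatible", "self_incompatible", "unknown")
RESTRICTIVENESS_LEVELS = ("unrestrictive", "low", "moderate", "high", "unknown")

_DELIMITERS = (",", "\t", ";")


class NetworkValidationError(ValueError):
    """A network or table violates its schema (negative weight, duplicate
    label, unknown categorical token, ...)."""


@dataclass(frozen=True)
class InteractionNetwork:
    """A weighted bipartite plant-pollinator network.

    Parameters
    ----------
    network_id
        Identifier of the community sample.
    plant_ids, pollinator_ids
        Ordered species/taxon labels; must be unique within each side.
    weights
        ``(n_plants, n_pollinators)`` array of non-negative visit counts.
    """

    network_id: str
    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "plant_ids", tuple(self.plant_ids))
        object.__setattr__(self, "pollinator_ids", tuple(self.pollinator_ids))
        if w.ndim != 2:
            raise NetworkValidationError(
                f"{self.network_id}: weights must be 2-dimensional"
            )
        if w.shape != (len(self.plant_ids), len(self.pollinator_ids)):
            raise NetworkValidationError(
                f"{self.network_id}: weight shape {w.shape} does not match "
                f"{len(self.plant_ids)} plants x {len(self.pollinator_ids)} pollinators"
            )
        _check_unique(self.plant_ids, "plant", self.network_id)
        _check_unique(self.pollinator_ids, "pollinator", self.network_id)
        if not np.all(np.isfinite(w)):
            raise NetworkValidationError(f"{self.network_id}: non-finite weight")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise NetworkValidationError(
                f"{self.network_id}: negative weight at plant "
                f"{self.plant_ids[i]!r}, pollinator {self.pollinator_ids[j]!r}"
            )

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_ids)

    @property
    def size(self) -> int:
        """Network size: total number of vertices (plants + pollinators)."""
        return self.n_plants + self.n_pollinators

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def validate(self) -> "InteractionNetwork":
        """Drop all-zero rows/columns (never-observed taxa) and require at
        least one positive interaction.  Retained weights are untouched."""
        w = self.weights
        if w.size == 0 or not np.any(w > 0):
            raise NetworkValidationError(
                f"{self.network_id}: network has no positive interaction"
            )
        keep_r = np.any(w > 0, axis=1)
        keep_c = np.any(w > 0, axis=0)
        if keep_r.all() and keep_c.all():
            return self
        dropped_p = [p for p, k in zip(self.plant_ids, keep_r) if not k]
        dropped_a = [a for a, k in zip(self.pollinator_ids, keep_c) if not k]
        if dropped_p:
            logger.warning(
                "%s: dropping %d plant(s) with no interactions: %s",
                self.network_id, len(dropped_p), ", ".join(dropped_p),
            )
        if dropped_a:
            logger.warning(
                "%s: dropping %d pollinator(s) with no interactions: %s",
                self.network_id, len(dropped_a), ", ".join(dropped_a),
            )
        return InteractionNetwork(
            network_id=self.network_id,
            plant_ids=tuple(p for p, k in zip(self.plant_ids, keep_r) if k),
            pollinator_ids=tuple(a for a, k in zip(self.pollinator_ids, keep_c) if k),
            weights=w[np.ix_(keep_r, keep_c)],
        )


@dataclass(frozen=True)
class PlantTraitTable:
    """Per-species trait assignments with explicit ``unknown`` levels."""

    table: pd.DataFrame  # columns: species, ploidy, mating, restrictiveness

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True)
        required = ["species", "ploidy", "mating", "restrictiveness"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise NetworkValidationError(f"trait table missing columns {missing}")
        df = df[required].copy()
        for col, levels in (
            ("ploidy", PLOIDY_LEVELS),
            ("mating", MATING_LEVELS),
            ("restrictiveness", RESTRICTIVENESS_LEVELS),
        ):
            df[col] = (
                df[col].astype("string").str.strip().str.lower().fillna("unknown")
            )
            df.loc[df[col] == "", col] = "unknown"
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise NetworkValidationError(
                    f"trait table: unrecognized {col} token(s) {bad}"
                )
        df["species"] = df["species"].astype(str).str.strip()
        dup = df["species"].str.casefold().duplicated()
        if dup.any():
            raise NetworkValidationError(
                f"trait table: duplicate species {sorted(df.loc[dup, 'species'])}"
            )
        object.__setattr__(self, "table", df)

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, species: Iterable[str]) -> pd.DataFrame:
        """Trait rows for the given species, matching case-insensitively after
        whitespace normalization; unmatched species come back as unknowns."""
        keyed = self.table.set_index(self.table["species"].str.casefold())
        keys = [str(s).strip().casefold() for s in species]
        unmatched = [s for s, k in zip(species, keys) if k not in keyed.index]
        if unmatched:
            logger.warning(
                "%d species not in trait table (treated as unknown): %s",
                len(unmatched), ", ".join(map(str, unmatched[:10])),
            )
        out = keyed.reindex(keys)
        out["species"] = list(species)
        for col in ("ploidy", "mating", "restrictiveness"):
            out[col] = out[col].fillna("unknown")
        return out.reset_index(drop=True)


@dataclass(frozen=True)
class NetworkCovariates:
    """Per-network coordinates and bioclimatic covariates.

    bio4/bio15 are temperature/precipitation seasonality; bio10 is the mean
    temperature of the warmest quarter (deg C); bio18 the precipitation of the
    warmest quarter (mm).  Any of them may be missing (NaN).
    """

    table: pd.DataFrame  # index: network_id

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["network_id", "latitude", "longitude",
                    "bio4", "bio10", "bio15", "bio18"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise NetworkValidationError(f"covariate table missing columns {missing}")
        df = df[required].copy()
        df["network_id"] = df["network_id"].astype(str)
        if df["network_id"].duplicated().any():
            raise NetworkValidationError("covariate table: duplicate network_id")
        for c in required[1:]:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        lat, lon = df["latitude"], df["longitude"]
        if ((lat < -90) | (lat > 90)).any():
            raise NetworkValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise NetworkValidationError("longitude outside [-180, 180]")
        if (df["bio18"].dropna() < 0).any():
            raise NetworkValidationError("bio18 (precipitation) must be >= 0")
        object.__setattr__(self, "table", df.set_index("network_id"))

    def get(self, network_id: str) -> pd.Series | None:
        if network_id in self.table.index:
            return self.table.loc[network_id]
        return None


# ---------------------------------------------------------------------------
# Parsing


def _check_unique(labels: Sequence[str], side: str, network_id: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise NetworkValidationError(
                f"{network_id}: duplicate {side} label {lab!r}"
            )
        seen.add(lab)


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()
    first = header[0] if header else ""
    counts = {d: first.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise NetworkValidationError(f"{path}: could not detect delimiter")
    return best


def read_network(
    path: str | Path,
    *,
    delimiter: str | None = None,
    transpose: bool = False,
    network_id: str | None = None,
) -> InteractionNetwork:
    """Read a weighted interaction matrix from delimited text.

    Layout: pollinator labels in the header row, plant labels in the first
    column, numeric body.  ``transpose=True`` accepts the opposite
    orientation.  Empty rows/columns are dropped with a logged warning.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    if transpose:
        df = df.T
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise NetworkValidationError(
            f"{path}: non-numeric cell at plant {df.index[r]!r}, "
            f"pollinator {df.columns[c]!r}"
        )
    net = InteractionNetwork(
        network_id=network_id or path.stem,
        plant_ids=tuple(str(i).strip() for i in df.index),
        pollinator_ids=tuple(str(c).strip() for c in df.columns),
        weights=body.to_numpy(dtype=float),
    )
    return net.validate()


def write_network(network: InteractionNetwork, path: str | Path,
                  *, delimiter: str = ",") -> None:
    df = pd.DataFrame(network.weights, index=list(network.plant_ids),
                      columns=list(network.pollinator_ids))
    # integer-valued counts are written without a decimal point so that a
    # write/read round trip is bit-exact for them
    if np.allclose(network.weights, np.round(network.weights)):
        df = df.astype(int)
    df.to_csv(Path(path), sep=delimiter, encoding="utf-8")


def read_networks_dir(directory: str | Path, *, delimiter: str | None = None,
                      pattern: str = "*.csv") -> list[InteractionNetwork]:
    return [read_network(p, delimiter=delimiter)
            for p in sorted(Path(directory).glob(pattern))]


def read_trait_table(path: str | Path, *, delimiter: str | None = None) -> PlantTraitTable:
    """Read a species/ploidy/mating/restrictiveness table; blank cells map to
    ``unknown``, unrecognized level strings are an error."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return PlantTraitTable(df)


def write_trait_table(traits: PlantTraitTable, path: str | Path,
                      *, delimiter: str = ",") -> None:
    traits.table.to_csv(Path(path), sep=delimiter, index=False, encoding="utf-8")


def read_covariates(path: str | Path, *, delimiter: str | None = None) -> NetworkCovariates:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    return NetworkCovariates(df)


def write_covariates(cov: NetworkCovariates, path: str | Path,
                     *, delimiter: str = ",") -> None:
    cov.table.reset_index().to_csv(Path(path), sep=delimiter, index=False,
                                   encoding="utf-8")


# ---------------------------------------------------------------------------
# Transformations


def binarize(network: InteractionNetwork) -> InteractionNetwork:
    """Presence/absence view: every positive visit count becomes 1.

    Any positive record is an interaction (weights are visit counts), so the
    threshold is strictly greater than zero.  Idempotent.
    """
    return replace(network, weights=(network.weights > 0).astype(float))
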