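"""Packaged comparative dataset: species-average osteochondral measurements.

The table lists, per sampled species, the habitat (terrestrial or aquatic),
average adult body mass, average articular cartilage thickness of the humeral
head, and the number of specimens analysed per modality (histology, micro-CT,
biomechanics).  The horse breeds (Shetland pony and horse) are kept as two
records sharing a single binomial; counting species deduplicates on the
binomial name.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

# Pinned digest of the packaged TSV: detects silent fixture corruption.
_SPECIES_TABLE_SHA256 = (
    "24aa07c870dbd03f2afc794b39f9b720a09fbb6ae778484f0bb23a5f4490dfa1"
)

_COLUMNS = [
    "id",
    "species",
    "habitat",
    "body_mass_kg",
    "thickness_mm",
    "n_histology",
    "n_microct",
    "n_biomech",
]


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged data file does not match its pinned checksum."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species table.

    ``species_name`` carries both common name and binomial, e.g.
    ``"Harbor porpoise (Phocoena phocoena)"``; ``binomial`` is the
    parenthesised latin name used for deduplication.
    """

    species_name: str
    habitat: str
    body_mass_kg: float
    cartilage_thickness_mm: float
    n_histology: int
    n_microct: int
    n_biomech: int

    @property
    def binomial(self) -> str:
        m = re.search(r"\(([^)]+)\)", self.species_name)
        return m.group(1) if m else self.species_name

    def __post_init__(self):
        if self.habitat not in ("terrestrial", "aquatic"):
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.body_mass_kg <= 0 or self.cartilage_thickness_mm <= 0:
            raise ValueError("body mass and cartilage thickness must be positive")
        if min(self.n_histology, self.n_microct, self.n_biomech) < 0:
            raise ValueError("sample counts must be non-negative")


def _fixture_bytes() -> bytes:
    ref = resources.files("osteounit.data").joinpath("species_table.tsv")
    return ref.read_bytes()


def load_species_table(*, verify: bool = True) -> pd.DataFrame:
    """Load the packaged species table as a DataFrame.

    Parameters
    ----------
    verify : bool
        Check the packaged file against its pinned SHA-256 digest and raise
        :class:`FixtureIntegrityError` on mismatch.

    Returns
    -------
    pandas.DataFrame
        16 rows (two horse-breed records share one binomial), columns
        ``id, species, habitat, body_mass_kg, thickness_mm, n_histology,
        n_microct, n_biomech``.
    """
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _SPECIES_TABLE_SHA256:
            raise FixtureIntegrityError(
                "species_table.tsv does not match its pinned checksum "
                f"(got {digest})"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype={"id": str})
    if list(df.columns) != _COLUMNS:
        raise FixtureIntegrityError(f"unexpected columns {list(df.columns)}")
    for rec in species_records(df):
        pass  # SpeciesRecord.__post_init__ validates every row
    return df


def species_records(df: pd.DataFrame | None = None) -> list[SpeciesRecord]:
    """The table as a list of validated :class:`SpeciesRecord`."""
    if df is None:
        df = load_species_table()
    return [
        SpeciesRecord(
            species_name=r.species,
            habitat=r.habitat,
            body_mass_kg=float(r.body_mass_kg),
            cartilage_thickness_mm=float(r.thickness_mm),
            n_histology=int(r.n_histology),
            n_microct=int(r.n_microct),
            n_biomech=int(r.n_biomech),
        )
        for r in df.itertuples()
    ]


def unique_binomials(df: pd.DataFrame | None = None) -> list[str]:
    """Distinct latin binomials in table order (deduplicates horse breeds)."""
    seen: dict[str, None] = {}
    for rec in species_records(df):
        seen.setdefault(rec.binomial)
    return list(seen)
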