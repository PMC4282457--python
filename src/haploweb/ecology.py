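"""Site geochemistry and species-by-habitat accounting.

Groundwater collection sites carry temperature, electrical conductivity,
redox potential (Eh, mV) and dissolved sulphide (H2S, μM) measurements.
H2S was not measured at every site; where it is missing, it is inferred
from Eh via the quasi-linear relationship the measured sulphidic sites
exhibit, with predictions clamped at zero in the oxidized (positive-Eh)
regime. A site is sulphidic iff its (measured or inferred) H2S is
strictly positive; species are tallied as "sulphidic" if they occur at
one or more sulphidic sites — occasionally or exclusively — and as
"nonsulphidic-only" otherwise.

The package ships a site-table fixture typed verbatim from the source
field survey, including one duplicated row, which the parser preserves
and flags.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from scipy import stats

__all__ = [
    "SiteRecord",
    "RegressionModel",
    "HabitatSummary",
    "ScreeningRecord",
    "ScreeningTally",
    "read_site_table",
    "write_site_table",
    "packaged_site_table",
    "fit_eh_h2s",
    "infer_h2s",
    "classify_sulphidic",
    "species_habitat_tally",
    "read_screening_table",
    "write_screening_table",
    "screening_tally",
]

SCREENING_OUTCOMES = ("thiothrix", "other_bacteria", "negative")


@dataclass
class SiteRecord:
    """One site row: location, geochemistry and the species found there."""

    town: str
    location: str
    latitude: str
    longitude: str
    date: str
    temp_c: float
    ec_us_cm: float
    eh_mv: float
    h2s_um: float
    h2s_inferred: bool
    species: frozenset[str]
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.h2s_um < 0:
            raise ValueError(f"{self.location}: H2S must be >= 0")
        if not self.species:
            raise ValueError(f"{self.location}: species set must be non-empty")

    @property
    def site_id(self) -> str:
        return f"{self.town}/{self.location}"


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of H2S (μM) on Eh (mV) over measured sulphidic sites."""

    slope: float        # μM per mV, expected negative
    intercept: float    # μM
    r_value: float
    fitted_on: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.fitted_on)


@dataclass
class HabitatSummary:
    sulphidic_species: set[str]
    nonsulphidic_only_species: set[str]
    all_species: set[str]
    site_classification: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sulphidic_species & self.nonsulphidic_only_species:
            raise ValueError("habitat species sets must be disjoint")
        if self.sulphidic_species | self.nonsulphidic_only_species != self.all_species:
            raise ValueError("habitat species sets must partition all species")


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Parse a site TSV. Duplicated (town, location, date) rows are kept
    and flagged via ``duplicate_of``."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    expected = [
        "town", "location", "latitude", "longitude", "date", "temp_c",
        "ec_us_cm", "eh_mv", "h2s_um", "h2s_inferred", "species",
    ]
    if header != expected:
        raise ValueError(f"unexpected site-table header: {header}")
    records: list[SiteRecord] = []
    seen: dict[tuple[str, str, str], str] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        key = (f[0], f[1], f[4])
        rec = SiteRecord(
            town=f[0], location=f[1], latitude=f[2], longitude=f[3], date=f[4],
            temp_c=float(f[5]), ec_us_cm=float(f[6]), eh_mv=float(f[7]),
            h2s_um=float(f[8]), h2s_inferred=f[9].strip().lower() in ("yes", "true", "1"),
            species=frozenset(s.strip() for s in f[10].split(";") if s.strip()),
            duplicate_of=seen.get(key),
        )
        if key not in seen:
            seen[key] = rec.site_id
        records.append(rec)
    if not records:
        raise ValueError(f"no site records in {path}")
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path) -> None:
    lines = [
        "town\tlocation\tlatitude\tlongitude\tdate\ttemp_c\tec_us_cm\t"
        "eh_mv\th2s_um\th2s_inferred\tspecies"
    ]
    for r in records:
        lines.append(
            f"{r.town}\t{r.location}\t{r.latitude}\t{r.longitude}\t{r.date}\t"
            f"{r.temp_c:g}\t{r.ec_us_cm:g}\t{r.eh_mv:g}\t{r.h2s_um:g}\t"
            f"{'yes' if r.h2s_inferred else 'no'}\t{';'.join(sorted(r.species))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def packaged_site_table() -> list[SiteRecord]:
    """The site-table fixture shipped with the package."""
    res = importlib.resources.files("haploweb.data") / "dobrogea_sites.tsv"
    with importlib.resources.as_file(res) as p:
        return read_site_table(p)


def fit_eh_h2s(sites: Iterable[SiteRecord]) -> RegressionModel:
    """OLS of measured H2S on Eh, restricted to measured sulphidic sites.

    Measured zeros are excluded: the quasi-linear Eh–H2S relationship
    breaks down at positive Eh, where zero-clamping (see infer_h2s)
    handles the oxidized regime instead.
    """
    usable = [
        s for s in sites if not s.h2s_inferred and s.h2s_um > 0
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 sites with measured H2S > 0, got {len(usable)}"
        )
    xs = [s.eh_mv for s in usable]
    ys = [s.h2s_um for s in usable]
    res = stats.linregress(xs, ys)
    return RegressionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        fitted_on=tuple(s.site_id for s in usable),
    )


def infer_h2s(model: RegressionModel, eh_mv: float) -> float:
    """Predicted H2S (μM) at a given Eh, clamped at zero."""
    return max(0.0, model.slope * eh_mv + model.intercept)


def classify_sulphidic(site: SiteRecord) -> bool:
    """A site is sulphidic iff H2S (measured or inferred) is strictly > 0."""
    return site.h2s_um > 0.0


def species_habitat_tally(sites: TypingSequence[SiteRecord]) -> HabitatSummary:
    """Partition species into sulphidic vs nonsulphidic-only.

    A species counts as sulphidic if it occurs at >= 1 sulphidic site,
    even if it also occurs at nonsulphidic ones ("occasionally or
    exclusively"); the remainder are restricted to nonsulphidic areas.
    """
    all_species: set[str] = set()
    sulphidic: set[str] = set()
    classification: dict[str, bool] = {}
    for s in sites:
        is_s = classify_sulphidic(s)
        classification[s.site_id] = is_s
        all_species |= s.species
        if is_s:
            sulphidic |= s.species
    return HabitatSummary(
        sulphidic_species=sulphidic,
        nonsulphidic_only_species=all_species - sulphidic,
        all_species=all_species,
        site_classification=classification,
    )


# ---------------------------------------------------------------------------
# specimen screening table


@dataclass(frozen=True)
class ScreeningRecord:
    """One screened specimen: host identity and PCR screening outcome."""

    specimen_id: str
    site_id: str
    species: str
    outcome: str  # thiothrix | other_bacteria | negative
    clade: str = "."

    def __post_init__(self) -> None:
        if self.outcome not in SCREENING_OUTCOMES:
            raise ValueError(
                f"{self.specimen_id}: outcome must be one of {SCREENING_OUTCOMES}"
            )


@dataclass(frozen=True)
class ScreeningTally:
    thiothrix_positive: int
    other_bacteria: int
    negative: int
    total: int


def read_screening_table(path: str | Path) -> list[ScreeningRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != [
        "specimen_id", "site_id", "species", "outcome",
    ]:
        raise ValueError(f"unexpected screening-table header in {path}")
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        out.append(
            ScreeningRecord(
                specimen_id=f[0], site_id=f[1], species=f[2], outcome=f[3],
                clade=f[4] if len(f) > 4 else ".",
            )
        )
    return out


def write_screening_table(
    records: Iterable[ScreeningRecord], path: str | Path
) -> None:
    lines = ["specimen_id\tsite_id\tspecies\toutcome\tclade"]
    for r in records:
        lines.append(
            f"{r.specimen_id}\t{r.site_id}\t{r.species}\t{r.outcome}\t{r.clade}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def screening_tally(records: TypingSequence[ScreeningRecord]) -> ScreeningTally:
    """Exhaustive partition of screened specimens by PCR outcome."""
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate specimen ids: {dup}")
    n_thio = sum(1 for r in records if r.outcome == "thiothrix")
    n_other = sum(1 for r in records if r.outcome == "other_bacteria")
    n_neg = sum(1 for r in records if r.outcome == "negative")
    return ScreeningTally(
        thiothrix_positive=n_thio,
        other_bacteria=n_other,
        negative=n_neg,
        total=len(records),
    )
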