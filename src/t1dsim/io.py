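"""Readers, writers and run configuration.

Country input bundles travel as long-format CSV with columns
``(country_id, metric, age, year, value)`` where metric is one of
``population, bg_mortality, incidence, nondx_rate, smr``.  Burden
results are written as tidy CSV ``(country_id, quantity, age, year,
value)`` plus a JSON summary of headline totals per year.  Every output
embeds the configuration hash and seed so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .markov import BurdenResult, CountryInputs
from .surfaces import AgeYearSurface

BUNDLE_METRICS = {
    "population": "persons",
    "bg_mortality": "probability",
    "incidence": "per100k_py",
    "nondx_rate": "probability",
    "smr": "dimensionless",
}


def read_country_bundle(path: str | Path, region: str, income_group: str,
                        country_id: str | None = None) -> CountryInputs:
    """Load one country's surfaces from a long-format bundle CSV."""
    df = pd.read_csv(path, comment="#")
    required = {"country_id", "metric", "age", "year", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: bundle CSV must have columns {sorted(required)}"
        )
    ids = df["country_id"].unique()
    if country_id is None:
        if len(ids) != 1:
            raise ValidationError(f"{path}: bundle holds several countries {list(ids)}; "
                                  "pass country_id")
        country_id = str(ids[0])
    df = df[df["country_id"] == country_id]
    surfaces = {}
    for metric, unit in BUNDLE_METRICS.items():
        sub = df[df["metric"] == metric]
        if sub.empty:
            raise ValidationError(f"{path}: bundle is missing metric {metric!r}")
        surfaces[metric] = AgeYearSurface.from_long(sub, unit)
    return CountryInputs(
        country_id=country_id, region=region, income_group=income_group,
        population=surfaces["population"],
        background_mortality=surfaces["bg_mortality"],
        incidence=surfaces["incidence"],
        nondx_rate=surfaces["nondx_rate"],
        smr=surfaces["smr"],
    )


def write_country_bundle(inputs: CountryInputs, path: str | Path) -> None:
    frames = [
        inputs.population.to_long(inputs.country_id, "population"),
        inputs.background_mortality.to_long(inputs.country_id, "bg_mortality"),
        inputs.incidence.to_long(inputs.country_id, "incidence"),
        inputs.nondx_rate.to_long(inputs.country_id, "nondx_rate"),
        inputs.smr.to_long(inputs.country_id, "smr"),
    ]
    pd.concat(frames).to_csv(path, index=False)


BURDEN_QUANTITIES = ("prevalence", "incident_diagnosed", "deaths_onset_nondx",
                     "deaths_after_dx", "deaths_after_dx_excess", "deaths_background")


def write_burden_csv(burden: BurdenResult, path: str | Path,
                     header_comment: str = "") -> None:
    """Tidy CSV export of every burden quantity, one row per cell."""
    frames = []
    for quantity in BURDEN_QUANTITIES:
        surf: AgeYearSurface = getattr(burden, quantity)
        frame = surf.to_long(burden.country_id, quantity)
        frame = frame.rename(columns={"metric": "quantity"})
        frames.append(frame)
    out = pd.concat(frames)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


def write_summary_json(burden: BurdenResult, path: str | Path,
                       meta: dict | None = None) -> dict:
    """JSON summary of headline totals per year; returns the payload."""
    summary = {
        "country_id": burden.country_id,
        "meta": meta or {},
        "years": burden.summary_frame().to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


@dataclass
class RunConfig:
    """Validated run configuration for the command line.

    ``scenario`` and ``haly`` blocks are optional and passed through to
    the projection and HALY stages.
    """

    bundle: str
    region: str
    income_group: str
    first_year: int
    last_year: int
    output_dir: str
    seed: int = 0
    country_id: str | None = None
    scenario: dict = field(default_factory=dict)
    haly: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: not valid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config fields {sorted(unknown)}")
        missing = {"bundle", "region", "income_group", "first_year", "last_year",
                   "output_dir"} - set(raw)
        if missing:
            raise ValidationError(f"{path}: missing config fields {sorted(missing)}")
        cfg = cls(**raw)
        bundle = Path(path).parent / cfg.bundle
        if not bundle.exists():
            raise ValidationError(f"{path}: bundle file {cfg.bundle!r} does not exist")
        cfg.bundle = str(bundle)
        if cfg.last_year < cfg.first_year:
            raise ValidationError(f"{path}: last_year before first_year")
        return cfg

    def digest(self) -> str:
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]
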