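"""Steady-state mass-balance estimation of per-OTU net growth rates.

A semi-continuous reactor of working volume ``Vc`` exchanges a fixed volume
of well-mixed liquor for fresh feed every ``exchange_interval`` days, giving
a volumetric exchange rate ``Q = exchange_volume / exchange_interval`` and a
solids retention time ``SRT = Vc / Q``. Because the reactor is completely
mixed, the fraction of volume discarded equals the fraction of solids
discarded, so SRT and hydraulic residence time coincide.

For taxon ``x`` with reactor standing stock ``N_x = Vc * Cc * p_xc`` (VSS
approximates total cell mass; ``p`` is 16S relative abundance), the balance

    dN_x/dt = (feed in) - (discard out) + mu_x * N_x

at steady state gives the estimator

    mu_x = 1/SRT - (Qf * Cf * p_xf) / (Vc * Cc * p_xc)   [1/d]

bounded above by the dilution rate ``1/SRT``, attained exactly when the
taxon is absent from the feed. A taxon present in the feed but undetected in
the reactor has been washed out (its mu is below what the SRT can retain)
and gets an explicit status instead of a pseudocount-derived sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .otu_io import RelAbundanceTable

__all__ = [
    "ReactorConfig",
    "GrowthStatus",
    "GrowthRateRecord",
    "compute_srt",
    "compute_growth_rate",
    "compute_growth_table",
    "assess_steady_state",
    "write_growth_table",
    "load_reactor_config",
    "expI_config",
    "expII_configs",
]


@dataclass(frozen=True)
class ReactorConfig:
    """Operating parameters of one semi-continuous reactor.

    Attributes
    ----------
    vc_ml : working volume [mL]
    exchange_volume_ml : volume discarded and replaced per event [mL]
    exchange_interval_d : time between exchange events [d]
    cf_g_per_l : feed VSS concentration [g/L]
    cc_g_per_l : reactor VSS concentration [g/L]
    cd_g_per_l : discarded-stream VSS concentration [g/L]; defaults to the
        reactor concentration (well-mixed discard).
    """

    vc_ml: float
    exchange_volume_ml: float
    exchange_interval_d: float
    cf_g_per_l: float = 0.0
    cc_g_per_l: float = 0.0
    cd_g_per_l: float | None = None

    def __post_init__(self) -> None:
        if self.vc_ml <= 0:
            raise ValueError("working volume must be positive")
        if not 0 < self.exchange_volume_ml <= self.vc_ml:
            raise ValueError("exchange volume must be in (0, Vc]")
        if self.exchange_interval_d <= 0:
            raise ValueError("exchange interval must be positive")
        for name in ("cf_g_per_l", "cc_g_per_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cd_g_per_l is not None and self.cd_g_per_l < 0:
            raise ValueError("cd_g_per_l must be non-negative")

    @property
    def q_ml_per_d(self) -> float:
        """Volumetric feed/discard rate Qf = Qd [mL/d]."""
        return self.exchange_volume_ml / self.exchange_interval_d

    @property
    def srt_d(self) -> float:
        return compute_srt(self)

    @property
    def cd_effective(self) -> float:
        return self.cc_g_per_l if self.cd_g_per_l is None else self.cd_g_per_l

    def with_cc(self, cc_g_per_l: float) -> "ReactorConfig":
        """Copy with the reactor VSS replaced (e.g. by a final-day measurement)."""
        return replace(self, cc_g_per_l=cc_g_per_l)


def compute_srt(cfg: ReactorConfig) -> float:
    """Solids retention time [d]: working volume over volumetric exchange rate."""
    return cfg.vc_ml / cfg.q_ml_per_d


class GrowthStatus(str, Enum):
    ESTIMATED = "estimated"
    WASHED_OUT = "washed_out"
    ABSENT_EVERYWHERE = "absent_everywhere"


@dataclass(frozen=True)
class GrowthRateRecord:
    """Estimated net growth rate for one OTU.

    ``mu_per_d`` is defined only for status ``estimated``; washed-out OTUs
    (detected in feed, absent from reactor) and OTUs absent from both
    streams carry ``None``.
    """

    otu_id: str
    mu_per_d: float | None
    status: GrowthStatus
    p_reactor: float
    p_feed: float
    taxonomy: str = ""
    steady_state_flag: bool | None = None  # True = CV warning; None = not assessed

    @property
    def mu(self) -> float | None:  # short alias used throughout
        return self.mu_per_d


def compute_growth_rate(
    p_reactor: float,
    p_feed: float,
    cfg: ReactorConfig,
    *,
    otu_id: str = "",
    taxonomy: str = "",
) -> GrowthRateRecord:
    """Estimate one OTU's net growth rate from feed/reactor abundances.

    mu = 1/SRT - (Qf*Cf*p_feed) / (Vc*Cc*p_reactor). Units: Q in mL/d and V
    in mL, C in g/L on both numerator and denominator, so the unit factors
    cancel and mu is in 1/d.
    """
    if not 0.0 <= p_reactor <= 1.0:
        raise ValueError(f"p_reactor must be in [0, 1], got {p_reactor}")
    if not 0.0 <= p_feed <= 1.0:
        raise ValueError(f"p_feed must be in [0, 1], got {p_feed}")
    if p_reactor == 0.0:
        status = GrowthStatus.WASHED_OUT if p_feed > 0 else GrowthStatus.ABSENT_EVERYWHERE
        return GrowthRateRecord(otu_id, None, status, p_reactor, p_feed, taxonomy)
    if cfg.cc_g_per_l <= 0:
        raise ValueError(
            "reactor VSS (cc_g_per_l) must be positive to estimate growth rates"
        )
    srt = compute_srt(cfg)
    influx = cfg.q_ml_per_d * cfg.cf_g_per_l * p_feed
    standing = cfg.vc_ml * cfg.cc_g_per_l * p_reactor
    mu = 1.0 / srt - influx / standing
    return GrowthRateRecord(otu_id, mu, GrowthStatus.ESTIMATED, p_reactor, p_feed, taxonomy)


def compute_growth_table(
    reactor: Mapping[str, float] | RelAbundanceTable,
    feed: Mapping[str, float] | RelAbundanceTable,
    cfg: ReactorConfig,
    *,
    reactor_sample: str | None = None,
    feed_sample: str | None = None,
    taxonomy: Mapping[str, str] | None = None,
    steady_state_flags: Mapping[str, bool] | None = None,
) -> list[GrowthRateRecord]:
    """Per-OTU growth rates for a reactor/feed column pair.

    Columns may be given as ``{otu_id: fraction}`` mappings or as
    :class:`RelAbundanceTable` objects together with a sample id. The OTU
    universe is the outer join of both columns; an OTU missing from one
    column has fraction zero there.
    """
    tax: dict[str, str] = dict(taxonomy or {})
    if isinstance(reactor, RelAbundanceTable):
        tax.update(reactor.taxonomy_map())
        reactor = reactor.column(reactor_sample if reactor_sample is not None else reactor.sample_ids[-1])
    if isinstance(feed, RelAbundanceTable):
        tax = {**feed.taxonomy_map(), **tax}
        feed = feed.column(feed_sample if feed_sample is not None else feed.sample_ids[-1])
    otus = list(reactor.keys()) + [o for o in feed.keys() if o not in reactor]
    flags = steady_state_flags or {}
    records = []
    for otu in otus:
        rec = compute_growth_rate(
            reactor.get(otu, 0.0), feed.get(otu, 0.0), cfg,
            otu_id=otu, taxonomy=tax.get(otu, ""),
        )
        if otu in flags:
            rec = replace(rec, steady_state_flag=bool(flags[otu]))
        records.append(rec)
    return records


def assess_steady_state(
    series: RelAbundanceTable, cv_threshold: float = 0.3
) -> dict[str, bool]:
    """Flag OTUs whose abundance still drifts over the final sampling days.

    The steady-state assumption behind the mass-balance estimator is checked
    per OTU as the coefficient of variation (sample SD / mean) of its
    fraction across >= 3 final time points; CV above ``cv_threshold`` flags
    the OTU. An OTU absent from every time point is stable-absent (not
    flagged).
    """
    if series.n_samples < 3:
        raise ValueError("steady-state assessment needs >= 3 time points")
    flags: dict[str, bool] = {}
    for i, otu in enumerate(series.otu_ids):
        row = series.p[i]
        mean = row.mean()
        if mean == 0.0:
            flags[otu] = False
            continue
        cv = row.std(ddof=1) / mean
        flags[otu] = bool(cv > cv_threshold)
    return flags


def _fmt_mu(mu: float | None) -> str:
    if mu is None:
        return "NA"
    if mu == 0.0:
        return "0.000"
    return f"{mu:.4g}"


def write_growth_table(records: Iterable[GrowthRateRecord], path: str | Path) -> None:
    """Write growth-rate records as TSV (mu to 4 significant figures)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "otu_id\ttaxonomy\tp_reactor\tp_feed\tmu_per_day\tstatus\tsteady_state_flag\n"
        )
        for r in records:
            flag = "NA" if r.steady_state_flag is None else str(r.steady_state_flag).lower()
            fh.write(
                f"{r.otu_id}\t{r.taxonomy}\t{r.p_reactor:.6g}\t{r.p_feed:.6g}\t"
                f"{_fmt_mu(r.mu_per_d)}\t{r.status.value}\t{flag}\n"
            )


# ---------------------------------------------------------------------------
# Config files and experiment presets


def load_reactor_config(path: str | Path) -> ReactorConfig:
    """Load a ReactorConfig from YAML (or JSON, which YAML subsumes)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: reactor config must be a mapping")
    return ReactorConfig(**doc)


def save_reactor_config(cfg: ReactorConfig, path: str | Path) -> None:
    doc = {
        "vc_ml": cfg.vc_ml,
        "exchange_volume_ml": cfg.exchange_volume_ml,
        "exchange_interval_d": cfg.exchange_interval_d,
        "cf_g_per_l": cfg.cf_g_per_l,
        "cc_g_per_l": cfg.cc_g_per_l,
    }
    if cfg.cd_g_per_l is not None:
        doc["cd_g_per_l"] = cfg.cd_g_per_l
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def expI_config() -> ReactorConfig:
    """Experiment-I preset: 150 mL reactor, 3 mL exchanged every 2 d (SRT 100 d)."""
    return load_reactor_config(_data_path("reactor_expI.yml"))


def expII_configs() -> dict[str, ReactorConfig]:
    """Experiment-II SRT-sweep presets keyed by schedule label.

    Schedules span exchange volumes {8, 12, 32} mL and intervals
    {2, 1, 0.5} d in a 150 mL reactor, i.e. SRTs from 2.34375 to 37.5 d.
    """
    return {
        "srt_37.5d": load_reactor_config(_data_path("reactor_expII_srt37.5.yml")),
        "srt_12.5d": load_reactor_config(_data_path("reactor_expII_srt12.5.yml")),
        "srt_2.34d": load_reactor_config(_data_path("reactor_expII_srt2.34.yml")),
    }
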