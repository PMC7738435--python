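"""Synthetic semi-continuous fermenter communities with known ground truth.

The simulator propagates per-taxon biomass [mg] under the same operating
scheme the mass-balance estimator assumes: a well-mixed reactor of volume
``Vc`` where, every ``exchange_interval`` days, ``exchange_volume`` mL of
mixed liquor is discarded and replaced with fresh feed. Between events each
taxon follows first-order net growth ``N -> N * exp(mu_true * interval)``;
at an event the discard scales everything by ``(Vc - v)/Vc`` and the feed
adds ``v * Cf * feed_profile[x]`` mg. Feed-borne taxa (feed_profile > 0)
relax to a bounded fixed point provided ``exp(mu*tau) * (Vc - v)/Vc < 1``;
resident taxa (feed_profile = 0) follow a pure exponential between
dilutions. A ``continuous_limit`` mode integrates the corresponding ODE
``dN/dt = mu*N - N/SRT + F`` with fixed-step Euler, where the estimator is
exact.

Measurement layers reproduce what a sequencing-based study actually sees:
a multinomial draw of reads at finite depth for the reactor and feed
samples, and multiplicative lognormal noise on the VSS biomass proxy.
Biomass stands in for cell count, mirroring the VSS approximation the
estimator itself makes.

The reactor community sample is the pre-discard state of the final exchange
event — the withdrawn aliquot is the sample, as in the emulated operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .egmb_core import (
    GrowthRateRecord,
    ReactorConfig,
    compute_growth_table,
    compute_srt,
    save_reactor_config,
)
from .otu_io import (
    OtuTable,
    SampleMetadata,
    to_relative_abundance,
    write_otu_table,
    write_sample_metadata,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "sequence_sample",
    "default_community",
    "estimate_growth_rates",
    "recovery_interval",
    "make_fixture",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic reactor run.

    ``mu_true`` [1/d] and ``feed_profile`` (fractions of feed biomass,
    summing to 1 over feed-borne taxa) have one entry per taxon. Feed-borne
    taxa must satisfy ``mu_true < 1/SRT`` so the steady state is bounded.
    """

    n_taxa: int
    mu_true: np.ndarray
    feed_profile: np.ndarray
    cfg: ReactorConfig
    init_biomass_mg: np.ndarray
    t_end_d: float
    mode: str = "semi_continuous"  # or "continuous_limit"
    euler_dt_d: float = 0.01
    read_depth: int = 100_000
    vss_noise_cv: float = 0.05
    seed: int = 0
    taxonomy: tuple[str, ...] = ()
    taxon_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_true, dtype=float)
        fp = np.asarray(self.feed_profile, dtype=float)
        n0 = np.asarray(self.init_biomass_mg, dtype=float)
        if not (len(mu) == len(fp) == len(n0) == self.n_taxa):
            raise ValueError("mu_true, feed_profile, init_biomass_mg must have n_taxa entries")
        if np.any(fp < 0):
            raise ValueError("feed_profile entries must be non-negative")
        total = fp.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"feed_profile must sum to 1 over feed-borne taxa (got {total})")
        if np.any(n0 < 0):
            raise ValueError("initial biomass must be non-negative")
        if self.mode not in {"semi_continuous", "continuous_limit"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        srt = compute_srt(self.cfg)
        bad = np.where((fp > 0) & (mu >= 1.0 / srt))[0]
        if bad.size:
            raise ValueError(
                f"taxon {self._id(bad[0])} is feed-borne with mu_true >= 1/SRT "
                f"({mu[bad[0]]:.4g} >= {1.0 / srt:.4g}); its steady state is unbounded"
            )
        ids = self.taxon_ids or tuple(f"OTU{i + 1}" for i in range(self.n_taxa))
        tax = self.taxonomy or tuple("" for _ in range(self.n_taxa))
        if len(ids) != self.n_taxa or len(tax) != self.n_taxa:
            raise ValueError("taxon_ids/taxonomy must have n_taxa entries")
        for name, arr in (("mu_true", mu), ("feed_profile", fp), ("init_biomass_mg", n0)):
            arr = arr.copy()
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "taxon_ids", tuple(ids))
        object.__setattr__(self, "taxonomy", tuple(tax))

    def _id(self, i: int) -> str:
        return self.taxon_ids[i] if self.taxon_ids else f"OTU{i + 1}"

    @property
    def srt_d(self) -> float:
        return compute_srt(self.cfg)

    def analytic_steady_state(self) -> np.ndarray:
        """Per-taxon steady-state biomass [mg].

        ``continuous_limit``: N* = F / (D - mu) with D = 1/SRT and influx
        F = Qf*Cf*feed_profile [mg/d]. ``semi_continuous``: post-feed fixed
        point N* = f / (1 - exp(mu*tau)*(Vc-v)/Vc) with per-event feed mass
        f = v*Cf*feed_profile [mg]. Resident taxa have N* = 0 (they decay
        under dilution unless mu exceeds the dilution rate).
        """
        cfg = self.cfg
        fp = self.feed_profile
        mu = self.mu_true
        out = np.zeros(self.n_taxa)
        borne = fp > 0
        if self.mode == "continuous_limit":
            f_rate = cfg.q_ml_per_d * cfg.cf_g_per_l * fp  # mg/d
            d = 1.0 / self.srt_d
            out[borne] = f_rate[borne] / (d - mu[borne])
        else:
            tau = cfg.exchange_interval_d
            keep = (cfg.vc_ml - cfg.exchange_volume_ml) / cfg.vc_ml
            f_event = cfg.exchange_volume_ml * cfg.cf_g_per_l * fp  # mg/event
            g = np.exp(mu * tau) * keep
            out[borne] = f_event[borne] / (1.0 - g[borne])
        return out


@dataclass(frozen=True)
class SimResult:
    """Trajectory, sequenced samples, VSS series, and the generating truth."""

    times_d: np.ndarray
    biomass_mg: np.ndarray  # (n_taxa, n_times)
    reactor_sample_biomass_mg: np.ndarray  # pre-discard state at final event
    final_counts: OtuTable  # samples: "reactor", "feed"
    vss_true_g_per_l: np.ndarray
    vss_measured_g_per_l: np.ndarray
    cc_measured_g_per_l: float  # noisy VSS at the reactor sampling point
    truth: pd.DataFrame  # taxon, mu_true, feed_fraction, n_star_mg
    config: SimConfig


def sequence_sample(
    biomass_mg: np.ndarray, read_depth: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Multinomial draw of ``read_depth`` reads with probabilities
    proportional to biomass; deterministic under a fixed seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    biomass_mg = np.asarray(biomass_mg, dtype=float)
    total = biomass_mg.sum()
    if total <= 0:
        raise ValueError("cannot sequence a sample with zero total biomass")
    return rng.multinomial(int(read_depth), biomass_mg / total)


def _simulate_semi(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cfg = config.cfg
    tau = cfg.exchange_interval_d
    keep = (cfg.vc_ml - cfg.exchange_volume_ml) / cfg.vc_ml
    feed_mass = cfg.exchange_volume_ml * cfg.cf_g_per_l * config.feed_profile  # mg
    grow = np.exp(config.mu_true * tau)
    n_events = max(1, int(round(config.t_end_d / tau)))
    n = config.init_biomass_mg.astype(float).copy()
    times = np.empty(n_events + 1)
    traj = np.empty((config.n_taxa, n_events + 1))
    times[0] = 0.0
    traj[:, 0] = n
    pre_discard = n
    for k in range(1, n_events + 1):
        n = n * grow          # first-order net growth over the interval
        pre_discard = n.copy()  # withdrawn aliquot == community sample
        n = n * keep + feed_mass  # well-mixed discard, then feed
        times[k] = k * tau
        traj[:, k] = n
    return times, traj, pre_discard


def _simulate_continuous(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cfg = config.cfg
    d = 1.0 / config.srt_d
    f_rate = cfg.q_ml_per_d * cfg.cf_g_per_l * config.feed_profile  # mg/d
    dt = config.euler_dt_d
    n_steps = max(1, int(round(config.t_end_d / dt)))
    n = config.init_biomass_mg.astype(float).copy()
    rate = config.mu_true - d
    # record ~200 points regardless of step count
    stride = max(1, n_steps // 200)
    rec_idx = list(range(0, n_steps + 1, stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    times = np.array([i * dt for i in rec_idx])
    traj = np.empty((config.n_taxa, len(rec_idx)))
    pos = 0
    for step in range(n_steps + 1):
        if step == rec_idx[pos]:
            traj[:, pos] = n
            pos += 1
            if pos == len(rec_idx):
                pos -= 1
        if step < n_steps:
            n = n + dt * (rate * n + f_rate)
    return times, traj, traj[:, -1].copy()


def simulate(config: SimConfig) -> SimResult:
    """Run the reactor-community simulation defined by ``config``.

    Returns the biomass trajectory, a sequenced reactor/feed sample pair at
    the end of the run, the (noisy) VSS series, and a truth table carrying
    ``mu_true``, feed fractions, and the analytic steady-state biomass.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "semi_continuous":
        times, traj, reactor_biomass = _simulate_semi(config)
    else:
        times, traj, reactor_biomass = _simulate_continuous(config)
    if not np.all(np.isfinite(traj)):
        bad = np.where(~np.isfinite(traj).all(axis=1))[0][0]
        raise ValueError(f"taxon {config.taxon_ids[bad]} diverged (non-finite biomass)")

    vss_true = traj.sum(axis=0) / config.cfg.vc_ml  # mg/mL == g/L
    noise = rng.lognormal(mean=0.0, sigma=config.vss_noise_cv, size=vss_true.size)
    vss_measured = vss_true * noise

    cc_true = reactor_biomass.sum() / config.cfg.vc_ml
    cc_measured = float(cc_true * rng.lognormal(0.0, config.vss_noise_cv))

    reactor_reads = sequence_sample(reactor_biomass, config.read_depth, rng)
    borne = config.feed_profile > 0
    if borne.any():
        feed_reads = sequence_sample(config.feed_profile, config.read_depth, rng)
    else:
        feed_reads = np.zeros(config.n_taxa, dtype=np.int64)
    counts = np.column_stack([reactor_reads, feed_reads]).astype(np.int64)
    final_counts = OtuTable(
        otu_ids=config.taxon_ids,
        taxonomy=config.taxonomy,
        counts=counts,
        sample_ids=("reactor", "feed"),
    )
    truth = pd.DataFrame(
        {
            "taxon": list(config.taxon_ids),
            "mu_true": config.mu_true,
            "feed_fraction": config.feed_profile,
            "n_star_mg": config.analytic_steady_state(),
        }
    )
    return SimResult(
        times_d=times,
        biomass_mg=traj,
        reactor_sample_biomass_mg=reactor_biomass,
        final_counts=final_counts,
        vss_true_g_per_l=vss_true,
        vss_measured_g_per_l=vss_measured,
        cc_measured_g_per_l=cc_measured,
        truth=truth,
        config=config,
    )


def estimate_growth_rates(result: SimResult, *, use_measured_vss: bool = True) -> list[GrowthRateRecord]:
    """Run the mass-balance estimator on a simulation's sequenced samples.

    The reactor VSS entering the estimator is the noisy measured value by
    default (the realistic case); ``use_measured_vss=False`` uses the exact
    simulated concentration instead.
    """
    rel = to_relative_abundance(result.final_counts)
    cc = result.cc_measured_g_per_l if use_measured_vss else float(
        result.reactor_sample_biomass_mg.sum() / result.config.cfg.vc_ml
    )
    cfg = result.config.cfg.with_cc(cc)
    return compute_growth_table(
        rel, rel, cfg, reactor_sample="reactor", feed_sample="feed"
    )


def recovery_interval(srt_d: float, max_abs_mu: float, resolution: float = 0.1) -> float:
    """Exchange interval for parameter-recovery studies [d].

    The steady-state estimator is exact only in the continuous limit, and
    the leading discretization bias for a rate mu is ~|mu|*tau/2 per event
    interval tau. The interval must therefore resolve both the dilution
    process (tau <= SRT/50) and the fastest kinetic rate in the community
    (tau <= resolution/|mu|_max, i.e. <=5% bias at the default 0.1).
    """
    if srt_d <= 0:
        raise ValueError("srt_d must be positive")
    tau = srt_d / 50.0
    if max_abs_mu > 0:
        tau = min(tau, resolution / max_abs_mu)
    return tau


# ---------------------------------------------------------------------------
# Community construction

_WAS_LINEAGES = [
    "Bacteria;Bacteroidetes;Chitinophagia;Chitinophagales;Chitinophagaceae;Terrimonas",
    "Bacteria;Acidobacteria;Blastocatellia;Bryobacterales;Bryobacteraceae;Bryobacter",
    "Bacteria;Bacteroidetes;Cytophagia;Cytophagales;Microscillaceae;uncultured",
    "Bacteria;Proteobacteria;Betaproteobacteria;Rhodocyclales;Zoogloeaceae;Zoogloea",
    "Bacteria;Bacteroidetes;Saprospiria;Saprospirales;Saprospiraceae;uncultured",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;uncultured",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;uncultured",
]
_FERMENTER_LINEAGES = [
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Tannerellaceae;Parabacteroides",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Rikenellaceae;uncultured",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prolixibacteraceae;Microbacter",
    "Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;uncultured",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Paludibacteraceae;Paludibacter",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Porphyromonadaceae;Macellibacteroides",
]
_SYNTROPH_LINEAGES = [
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Syntrophomonadaceae;Syntrophomonas",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae;Smithella",
]
_METHANOGEN_LINEAGES = [
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
]


def default_community(
    cfg: ReactorConfig,
    n_taxa: int = 30,
    seed: int = 0,
    *,
    t_end_d: float | None = None,
    read_depth: int = 100_000,
    vss_noise_cv: float = 0.05,
    mode: str = "semi_continuous",
) -> SimConfig:
    """A realistic fermenter community for the given operating schedule.

    Roughly 60% of taxa are feed-borne sludge biomass being decomposed
    (mu_true uniform in [-0.8, -0.02] /d), a few are feed-borne slow growers
    (0 < mu_true < 0.5/SRT), and the rest are reactor residents — syntrophs,
    methanogens and fermenters growing at the dilution rate, the washout
    equilibrium the operating scheme enforces. Feed fractions are Dirichlet-
    distributed over feed-borne taxa; residents start at 30 mg each and
    feed-borne taxa at their analytic steady state so the run begins near
    equilibrium and converges well within ``t_end_d`` (default 20*SRT).
    """
    if n_taxa < 8:
        raise ValueError("default community needs at least 8 taxa")
    rng = np.random.default_rng(seed)
    srt = compute_srt(cfg)
    n_was = int(round(0.6 * n_taxa))
    n_grower = max(2, int(round(0.1 * n_taxa)))
    n_resident = n_taxa - n_was - n_grower  # syntrophs + methanogens + fermenters

    mu = np.empty(n_taxa)
    fp = np.zeros(n_taxa)
    tax: list[str] = []
    mu[:n_was] = rng.uniform(-0.8, -0.02, size=n_was)
    mu[n_was:n_was + n_grower] = rng.uniform(0.05 / srt, 0.5 / srt, size=n_grower)
    # residents: exact washout equilibrium of the discrete event map,
    # exp(mu*tau)*(Vc-v)/Vc = 1, i.e. constant biomass between samplings
    keep = (cfg.vc_ml - cfg.exchange_volume_ml) / cfg.vc_ml
    mu_neutral = -np.log(keep) / cfg.exchange_interval_d
    mu[n_was + n_grower:] = mu_neutral

    borne = n_was + n_grower
    fp[:borne] = rng.dirichlet(np.full(borne, 5.0))

    for i in range(n_was):
        tax.append(_WAS_LINEAGES[i % len(_WAS_LINEAGES)])
    for i in range(n_grower):
        tax.append(_FERMENTER_LINEAGES[i % len(_FERMENTER_LINEAGES)])
    pools = _SYNTROPH_LINEAGES + _METHANOGEN_LINEAGES + _FERMENTER_LINEAGES
    for i in range(n_resident):
        tax.append(pools[i % len(pools)])

    probe = SimConfig(
        n_taxa=n_taxa, mu_true=mu, feed_profile=fp, cfg=cfg,
        init_biomass_mg=np.zeros(n_taxa), t_end_d=1.0, mode=mode,
    )
    init = probe.analytic_steady_state()
    init[borne:] = 30.0  # mg per resident taxon
    return SimConfig(
        n_taxa=n_taxa,
        mu_true=mu,
        feed_profile=fp,
        cfg=cfg,
        init_biomass_mg=init,
        t_end_d=20.0 * srt if t_end_d is None else t_end_d,
        mode=mode,
        read_depth=read_depth,
        vss_noise_cv=vss_noise_cv,
        seed=seed,
        taxonomy=tuple(tax),
        taxon_ids=tuple(f"OTU{i + 1}" for i in range(n_taxa)),
    )


# ---------------------------------------------------------------------------
# Fixture generation

FIXTURE_PRESETS = ("toy", "expI_control", "expII_srt_sweep")


def _write_run(config: SimConfig, outdir: Path, condition: str) -> SimResult:
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate(config)
    write_otu_table(result.final_counts, outdir / "otu_table.tsv")
    write_sample_metadata(
        [
            SampleMetadata("reactor", "reactor", config.t_end_d, "reactor_rep", condition),
            SampleMetadata("feed", "feed", config.t_end_d, "feed_rep", condition),
        ],
        outdir / "metadata.tsv",
    )
    save_reactor_config(
        config.cfg.with_cc(round(result.cc_measured_g_per_l, 4)), outdir / "reactor.yml"
    )
    truth = result.truth.copy()
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return result


def make_fixture(preset: str, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a self-consistent fixture (OTU table, metadata, reactor config,
    truth table) for one of the packaged presets.

    ``toy``: 10 taxa under the 100-d-SRT schedule, short run. ``expI_control``:
    30 taxa, 150 mL / 3 mL / 2 d (SRT 100 d). ``expII_srt_sweep``: one reactor
    per schedule — 8 mL/2 d (SRT 37.5 d), 12 mL/1 d (12.5 d), 32 mL/0.5 d
    (2.34375 d) — in per-schedule subdirectories.
    """
    from .egmb_core import expI_config, expII_configs

    outdir = Path(outdir)
    written: dict[str, Path] = {}
    if preset == "toy":
        cfg = expI_config()
        config = default_community(cfg, n_taxa=10, seed=seed, t_end_d=40.0, read_depth=20_000)
        _write_run(config, outdir, "toy")
        written["toy"] = outdir
    elif preset == "expI_control":
        cfg = expI_config()
        config = default_community(cfg, n_taxa=30, seed=seed, t_end_d=40.0)
        _write_run(config, outdir, "expI_control")
        written["expI_control"] = outdir
    elif preset == "expII_srt_sweep":
        for label, cfg in expII_configs().items():
            sub = outdir / label
            config = default_community(cfg, n_taxa=30, seed=seed)
            _write_run(config, sub, label)
            written[label] = sub
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    return written
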