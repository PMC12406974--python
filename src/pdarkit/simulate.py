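"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with its true
parameters recorded, so each fitter and statistic can be validated by
round-trip recovery:

* live/dead kinetic trajectories — exponential growth with lag-exponential
  death, optional post-onset proliferation arrest, and multiplicative
  lognormal measurement noise (fluorescence-like);
* genotype panels — knockout backgrounds attenuate the asymptotic lethal
  fraction by configurable factors, emulating PTBP1-KO, BCL2L12-KO and
  BAX/BAK-DKO dependence of a degrader-like drug;
* protein decay courses — exponential Pol IIA/IIO band intensities coupled
  to death onset so that death timing tracks Pol IIA loss with a fixed lag;
* pooled-screen guide counts — negative-binomial counts for T0/live/dead
  samples, 4 guides per gene plus 142 non-targeting controls, with
  configurable dead-fraction enrichment for effect genes.

All generators take an integer seed and are deterministic for a given
configuration; truth parameters travel with the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .flick import KineticTrajectory
from .kinetics import led_eval
from .screen import NONTARGETING, GuideCountTable

__all__ = [
    "LEDTruth",
    "SimConfig",
    "simulate_trajectory",
    "simulate_panel",
    "simulate_led_series",
    "simulate_decay_course",
    "simulate_screen_counts",
]

GENOTYPES = ("WT", "PTBP1-KO", "BCL2L12-KO", "BAX-BAK-DKO")


@dataclass
class LEDTruth:
    """Ground-truth LED parameters for one drug-dose, plus per-genotype
    attenuation of the asymptotic lethal fraction."""

    lf0: float = 0.02
    lfp: float = 0.85
    dr: float = 0.1
    do: float = 12.0
    arrest: bool = True
    #: genotype → factor in [0, 1] multiplying (LFP − LF0); 1 = no protection.
    genotype_factors: dict = field(default_factory=dict)

    def for_genotype(self, genotype: str) -> tuple[float, float, float, float]:
        f = self.genotype_factors.get(genotype, 1.0)
        return self.lf0, self.lf0 + (self.lfp - self.lf0) * f, self.dr, self.do


#: Untreated background death: low, slow, late — max LF ≈ 0.08, half the
#: 0.16 lethality threshold.
UNTREATED_TRUTH = LEDTruth(lf0=0.01, lfp=0.08, dr=0.05, do=24.0, arrest=False)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    noise_sd: float = 0.02          # lognormal sd of multiplicative count noise
    c0: float = 2000.0              # cells seeded per well
    untreated_doubling: float = 24.0  # hours
    timepoints: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 73.0, 2.0)  # 37 points over 72 h
    )
    drug_params: dict = field(default_factory=dict)  # (drug, dose) → LEDTruth
    # decay-course truth: Pol IIA / IIO half-lives and the death lag (hours)
    iia_thalf: float = 10.0
    iio_thalf: float = 3.0
    onset_lag: float = 11.0
    decay_death_rate: float = 6.0   # per hour; apoptotic death is rapid
    # screen layout
    n_genes: int = 1000
    guides_per_gene: int = 4
    n_nontargeting: int = 142
    nb_dispersion: float = 0.1
    mean_coverage: float = 500.0    # reads per guide
    library_size_sd: float = 0.2    # lognormal sd of per-sample depth
    effects: dict = field(default_factory=dict)  # gene → dead-fraction fold change


def _truth_for(cfg: SimConfig, drug: str, dose: float) -> LEDTruth:
    if drug == "untreated":
        return UNTREATED_TRUTH
    try:
        return cfg.drug_params[(drug, dose)]
    except KeyError:
        raise ValueError(f"no ground-truth parameters for ({drug!r}, {dose})") from None


def simulate_trajectory(
    cfg: SimConfig,
    genotype: str,
    drug: str,
    dose: float,
    rng: np.random.Generator | None = None,
) -> KineticTrajectory:
    """Simulate one live/dead trajectory from LED ground truth.

    The total population grows exponentially with the untreated doubling
    time; if the drug arrests proliferation, growth stops at death onset
    (doubling time → ∞ after DO).  The lethal fraction follows the LED
    truth with the plateau attenuated by the genotype's factor; dead =
    total · LF and live = total · (1 − LF), each then perturbed by
    multiplicative lognormal noise.
    """
    truth = _truth_for(cfg, drug, dose)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.timepoints, dtype=float)
    lf0, lfp, dr, do = truth.for_genotype(genotype)
    lf = led_eval(t, lf0, lfp, dr, do)
    growth_t = np.minimum(t, do) if truth.arrest else t
    total = cfg.c0 * np.exp2(growth_t / cfg.untreated_doubling)
    dead = total * lf
    live = total * (1.0 - lf)
    if cfg.noise_sd > 0:
        dead = dead * rng.lognormal(0.0, cfg.noise_sd, size=len(t))
        live = live * rng.lognormal(0.0, cfg.noise_sd, size=len(t))
    return KineticTrajectory(
        condition_id=f"{genotype}:{drug}:{dose:g}",
        genotype=genotype,
        drug=drug,
        dose=dose,
        times=t,
        live=live,
        dead=dead,
        meta={"seed": cfg.seed, "truth": asdict(truth)},
    )


def simulate_panel(cfg: SimConfig, genotypes=GENOTYPES) -> pd.DataFrame:
    """Simulate the full genotype × drug-dose panel as a long-format table.

    Every (drug, dose) in ``cfg.drug_params`` plus an untreated condition
    is simulated for every genotype.  The returned frame carries LF columns
    ready for LED fitting; truth parameters are in ``frame.attrs``.
    """
    rng = np.random.default_rng(cfg.seed)
    conditions = [("untreated", 0.0)] + sorted(cfg.drug_params)
    frames = []
    for drug, dose in conditions:
        for genotype in genotypes:
            traj = simulate_trajectory(cfg, genotype, drug, dose, rng=rng)
            df = traj.to_frame()
            df["LF"] = traj.lethal_fraction
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = cfg.seed
    out.attrs["truth"] = {f"{d}:{dose:g}": asdict(p) for (d, dose), p in cfg.drug_params.items()}
    return out


def simulate_led_series(
    truth: LEDTruth,
    times,
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
):
    """LED lethal-fraction samples with additive Gaussian noise on LF.

    Companion to the count-level generator for direct parameter-recovery
    tests of the LED fitter; returns ``(times, lf)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.asarray(times, dtype=float)
    lf = led_eval(t, truth.lf0, truth.lfp, truth.dr, truth.do)
    if noise_sd > 0:
        lf = np.clip(lf + rng.normal(0.0, noise_sd, size=len(t)), 0.0, 1.0)
    return t, lf


def simulate_decay_course(
    cfg: SimConfig,
    drug: str = "triptolide",
    dose: float = 1.0,
    decay_times=None,
    lf_times=None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Simulate coupled protein-decay, EU and death courses for one condition.

    Pol IIA and IIO band intensities decay exponentially with the
    configured half-lives; the EU-negative fraction rises as a logistic
    centered on the IIO half-life (transcription stops when elongating
    polymerase is lost); and death onset follows Pol IIA loss after the
    configured lag: DO = t_half(IIA) + onset_lag, with a steep death rate
    so the half-death time LF50 sits just ln2/DR after onset.

    Returns a dict with ``decay`` (time_h, iia, iio), ``eu`` (time_h,
    frac_eu_negative), ``lf`` (time_h, LF) frames and ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    t_dec = np.arange(0.0, 49.0, 2.0) if decay_times is None else np.asarray(decay_times, float)
    t_lf = np.arange(0.0, 96.1, 0.5) if lf_times is None else np.asarray(lf_times, float)

    iia = np.exp2(-t_dec / cfg.iia_thalf)
    iio = np.exp2(-t_dec / cfg.iio_thalf)
    if noise_sd > 0:
        iia = iia * rng.lognormal(0.0, noise_sd, size=len(t_dec))
        iio = iio * rng.lognormal(0.0, noise_sd, size=len(t_dec))
    # renormalize to the highest observed signal, as immunoblots are
    iia = iia / iia.max()
    iio = iio / iio.max()

    eu_neg = 1.0 / (1.0 + (cfg.iio_thalf / np.maximum(t_dec, 1e-9)) ** 4.0)
    eu_neg[t_dec == 0] = 0.0
    if noise_sd > 0:
        eu_neg = np.clip(eu_neg + rng.normal(0.0, noise_sd, size=len(t_dec)), 0.0, 1.0)

    do = cfg.iia_thalf + cfg.onset_lag
    lf = led_eval(t_lf, 0.0, 0.9, cfg.decay_death_rate, do)
    if noise_sd > 0:
        lf = np.clip(lf + rng.normal(0.0, noise_sd, size=len(t_lf)), 0.0, 1.0)

    truth = dict(
        iia_thalf=cfg.iia_thalf, iio_thalf=cfg.iio_thalf, onset_lag=cfg.onset_lag,
        death_onset=do, death_rate=cfg.decay_death_rate, drug=drug, dose=dose,
        seed=cfg.seed,
    )
    return {
        "decay": pd.DataFrame({"time_h": t_dec, "iia": iia, "iio": iio}),
        "eu": pd.DataFrame({"time_h": t_dec, "frac_eu_negative": eu_neg}),
        "lf": pd.DataFrame({"time_h": t_lf, "LF": lf}),
        "truth": truth,
    }


def simulate_screen_counts(cfg: SimConfig) -> GuideCountTable:
    """Simulate negative-binomial guide counts for T0/live/dead samples.

    Each guide gets a lognormal baseline abundance; the dead sample's
    expected abundance for guides of an effect gene is multiplied by the
    configured fold change (enrichment > 1 for death suppressors' guides
    accumulating in corpses, < 1 for depletion).  Per-sample library sizes
    are drawn lognormally to exercise depth normalization.  Counts are
    NB-distributed with the configured dispersion.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    guide_gene = np.repeat(genes, cfg.guides_per_gene).tolist()
    guide_gene += [NONTARGETING] * cfg.n_nontargeting
    guide_ids = [f"{g}_sg{i % cfg.guides_per_gene + 1}" for i, g in
                 enumerate(guide_gene[: cfg.n_genes * cfg.guides_per_gene])]
    guide_ids += [f"NT_sg{i + 1}" for i in range(cfg.n_nontargeting)]
    n_guides = len(guide_gene)

    base = rng.lognormal(mean=0.0, sigma=0.5, size=n_guides)
    base /= base.mean()

    effect = np.ones(n_guides)
    gene_arr = np.asarray(guide_gene)
    for gene, fold in cfg.effects.items():
        effect[gene_arr == gene] = fold

    alpha = cfg.nb_dispersion
    counts = {}
    for sample in ("T0", "live", "dead"):
        depth = rng.lognormal(0.0, cfg.library_size_sd)
        mu = base * cfg.mean_coverage * depth
        if sample == "dead":
            mu = mu * effect
        if alpha > 0:
            n_param = 1.0 / alpha
            counts[sample] = rng.negative_binomial(n_param, n_param / (n_param + mu))
        else:
            counts[sample] = rng.poisson(mu)

    guides = pd.DataFrame({"guide_id": guide_ids, "gene": guide_gene})
    table = GuideCountTable(
        guides=guides,
        counts=pd.DataFrame(counts, dtype=float),
        meta={"seed": cfg.seed, "effects": dict(cfg.effects)},
    )
    return table
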