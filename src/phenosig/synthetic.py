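"""Synthetic cohort generator with recorded ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes in real pharmacogenomic data:

* two correlated log-normal IC50 sources with a bimodal (sensitive /
  resistant) class structure and a discordant subgroup whose apparent class
  differs between sources;
* negative-binomial RNA-seq counts with log-normal gene base means, per-
  sample library-size factors and planted sign-split differential genes;
* a log10(TPM+1) matrix derived from the counts by within-sample scaling;
* exponential survival with a group-dependent hazard;
* a multi-drug IC50 panel with per-drug class effects.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_survival",
    "simulate_drug_panel",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated drug-sensitivity cohort.

    Defaults mirror the scale of a real two-source cisplatin cohort: 60
    sensitive and 55 resistant lines with a 35-line discordant pool, 2,000
    genes of which 30 carry a planted |log2FC| = 1.5 split evenly between
    up- and down-regulation in the resistant class.  IC50 class means are
    10 and 70 uM so the boundary between classes falls near 30 uM.
    """

    n_sensitive: int = 60
    n_resistant: int = 55
    n_discordant: int = 35
    n_genes: int = 2000
    n_signature_up: int = 15
    n_signature_down: int = 15
    signature_log2fc: float = 1.5
    nb_dispersion: float = 0.2
    libsize_log_sd: float = 0.2
    base_mean_log_mu: float = float(np.log(50.0))
    base_mean_log_sd: float = 1.2
    signature_min_base_mean: float = 20.0
    ic50_mu_sensitive: float = float(np.log(10.0))  # ln uM
    ic50_mu_resistant: float = float(np.log(70.0))  # ln uM
    ic50_log_sd: float = 0.15
    cross_source_noise_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_sensitive": self.n_sensitive,
            "n_resistant": self.n_resistant,
            "n_discordant": self.n_discordant,
            "n_genes": self.n_genes,
            "n_signature_up": self.n_signature_up,
            "n_signature_down": self.n_signature_down,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise ValueError("signature genes exceed n_genes")
        if self.signature_log2fc <= 0:
            raise ValueError("signature_log2fc must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_signature_up + self.n_signature_down > 0 and (
            self.n_sensitive == 0 or self.n_resistant == 0
        ):
            raise ValueError(
                "signature genes require samples in both the sensitive and "
                "resistant class"
            )


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to plant it."""

    ic50_a: pd.Series  # uM, indexed by cell-line id
    ic50_b: pd.Series  # uM
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    tpm: pd.DataFrame  # genes x samples, log10(TPM + 1)
    truth_labels: pd.Series  # id -> {sensitive, resistant, discordant}
    truth_genes: pd.Series  # gene id -> {+1, -1}
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def truth_up(self) -> set[str]:
        return set(self.truth_genes.index[self.truth_genes > 0])

    @property
    def truth_down(self) -> set[str]:
        return set(self.truth_genes.index[self.truth_genes < 0])


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"CL{i:0{width}d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full cohort (two IC50 sources, counts, log-TPM, truth).

    IC50s: each line carries a shared log-normal deviate plus independent
    per-source noise around its class mean; discordant lines take the
    sensitive mean in one source and the resistant mean in the other, half
    of the pool in each direction, so the IC50 plane shows the four blobs
    (concordant-low, concordant-high, and both discordant quadrants) seen
    in real two-source panels.

    Counts: NB with variance mu + dispersion * mu^2, library-size factors
    log-normal, planted +-signature_log2fc shifts between the sensitive and
    resistant classes for truth genes (discordant lines express at the
    sensitive baseline).  log10(TPM+1) is derived from the counts by
    per-sample total scaling with unit gene lengths.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = (
        ["sensitive"] * cfg.n_sensitive
        + ["resistant"] * cfg.n_resistant
        + ["discordant"] * cfg.n_discordant
    )
    n = len(labels)
    ids = _sample_ids(n)
    truth_labels = pd.Series(labels, index=ids, name="truth")

    lab = np.asarray(labels)
    mu_a = np.where(lab == "sensitive", cfg.ic50_mu_sensitive, cfg.ic50_mu_resistant)
    mu_b = mu_a.copy()
    disc = np.flatnonzero(lab == "discordant")
    half = len(disc) // 2
    mu_a[disc[:half]] = cfg.ic50_mu_sensitive
    mu_b[disc[:half]] = cfg.ic50_mu_resistant
    mu_a[disc[half:]] = cfg.ic50_mu_resistant
    mu_b[disc[half:]] = cfg.ic50_mu_sensitive

    shared = rng.normal(0.0, cfg.ic50_log_sd, n)
    ic50_a = pd.Series(
        np.exp(mu_a + shared + rng.normal(0.0, cfg.cross_source_noise_sd, n)),
        index=ids, name="ic50_a",
    )
    ic50_b = pd.Series(
        np.exp(mu_b + shared + rng.normal(0.0, cfg.cross_source_noise_sd, n)),
        index=ids, name="ic50_b",
    )

    genes = _gene_ids(cfg.n_genes)
    base = np.exp(rng.normal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, cfg.n_genes))
    signs = np.zeros(cfg.n_genes)
    signs[: cfg.n_signature_up] = 1.0
    signs[cfg.n_signature_up : cfg.n_signature_up + cfg.n_signature_down] = -1.0
    # planted biomarkers are detectably expressed: a signature gene drawn from
    # the deep low-expression tail would carry no recoverable signal and make
    # the planted-truth bookkeeping vacuous
    base[signs != 0] = np.maximum(base[signs != 0], cfg.signature_min_base_mean)
    # log2 shift applied to the resistant class only
    shift = np.zeros((cfg.n_genes, n))
    shift[:, lab == "resistant"] = (signs * cfg.signature_log2fc)[:, None]
    libf = np.exp(rng.normal(0.0, cfg.libsize_log_sd, n))
    mu = base[:, None] * np.exp2(shift) * libf[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts_arr = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts_arr, index=genes, columns=ids)

    totals = counts_arr.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    tpm = pd.DataFrame(
        np.log10(counts_arr / totals[None, :] * 1e6 + 1.0), index=genes, columns=ids
    )

    truth_genes = pd.Series(
        signs[signs != 0].astype(int),
        index=[g for g, s in zip(genes, signs) if s != 0],
        name="sign",
    )

    if cfg.missing_rate > 0:
        # knock one source's value out for a fraction of lines, to exercise
        # the merge filter downstream
        n_missing = int(round(cfg.missing_rate * n))
        victims = rng.choice(n, size=n_missing, replace=False)
        sources = rng.integers(0, 4, size=n_missing)
        if (sources == 2).any():
            counts = counts.astype(float)
        for idx, src in zip(victims, sources):
            sid = ids[idx]
            if src == 0:
                ic50_a.loc[sid] = np.nan
            elif src == 1:
                ic50_b.loc[sid] = np.nan
            elif src == 2:
                counts.loc[:, sid] = np.nan
            else:
                tpm.loc[:, sid] = np.nan

    return SyntheticCohort(
        ic50_a=ic50_a,
        ic50_b=ic50_b,
        counts=counts,
        tpm=tpm,
        truth_labels=truth_labels,
        truth_genes=truth_genes,
        config=cfg,
    )


def simulate_survival(
    groups: Mapping[str, str],
    hazard_ratio: float,
    baseline_rate: float = 0.2,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a group-dependent hazard.

    Event times are exponential with rate ``baseline_rate`` for the
    sensitive group and ``baseline_rate * hazard_ratio`` for the resistant
    group.  Censoring is an independent exponential tuned so that the
    expected censored fraction is ``censor_rate`` (P(C < T) = c/(c+lambda)
    for competing exponentials).  Returns columns (id, time, event, group).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    ids = list(groups)
    grp = np.asarray([groups[i] for i in ids])
    valid = {"sensitive", "resistant"}
    if not set(grp) <= valid:
        raise ValueError(f"groups must be binary {valid}, got {set(grp)}")
    rng = np.random.default_rng(seed)
    rate = np.where(grp == "resistant", baseline_rate * hazard_ratio, baseline_rate)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        mean_rate = float(rate.mean())
        c_rate = censor_rate / (1.0 - censor_rate) * mean_rate
        t_cens = rng.exponential(1.0 / c_rate, size=len(ids))
    else:
        t_cens = np.full(len(ids), np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {"id": ids, "time": time, "event": event, "group": grp}
    ).set_index("id")


def simulate_drug_panel(
    truth_labels: Mapping[str, str],
    drug_effects: Mapping[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell line x drug IC50 table with per-drug log2 class effects.

    Each drug's log IC50 is normal around a drug-specific baseline, with
    the resistant class shifted by ``drug_effects[drug]`` log2 units (so a
    +2 effect is a 4-fold geometric-mean increase in the resistant arm).
    Lines labelled neither sensitive nor resistant get the baseline mean.
    """
    for drug, eff in drug_effects.items():
        if not np.isfinite(eff):
            raise ValueError(f"non-finite effect for drug {drug!r}")
    ids = list(truth_labels)
    grp = np.asarray([truth_labels[i] for i in ids])
    rng = np.random.default_rng(seed)
    out = {}
    for drug in drug_effects:
        baseline = rng.normal(0.0, 1.0)
        shift = np.where(grp == "resistant", drug_effects[drug] * np.log(2.0), 0.0)
        out[drug] = np.exp(baseline + shift + rng.normal(0.0, noise_sd, len(ids)))
    return pd.DataFrame(out, index=pd.Index(ids, name="id"))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write a cohort in the delimited formats the dataio module reads.

    Emits ic50_a.csv / ic50_b.csv as (id, value) tables, counts.csv and
    tpm.csv as genes-in-rows matrices, and a truth sidecar with the planted
    labels and gene signs.  Returns a manifest of file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, series in (("ic50_a", cohort.ic50_a), ("ic50_b", cohort.ic50_b)):
        p = outdir / f"{name}.csv"
        series.rename("ic50").rename_axis("id").to_csv(p)
        paths[name] = str(p)
    for name, frame in (("counts", cohort.counts), ("tpm", cohort.tpm)):
        p = outdir / f"{name}.csv"
        frame.rename_axis("gene").to_csv(p)
        paths[name] = str(p)
    p = outdir / "truth_labels.csv"
    cohort.truth_labels.rename("label").rename_axis("id").to_csv(p)
    paths["truth_labels"] = str(p)
    p = outdir / "truth_genes.csv"
    cohort.truth_genes.rename("sign").rename_axis("gene").to_csv(p)
    paths["truth_genes"] = str(p)
    if cohort.config is not None:
        p = outdir / "synthetic_config.csv"
        pd.Series(asdict(cohort.config)).rename("value").rename_axis("key").to_csv(p)
        paths["synthetic_config"] = str(p)
    return paths
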