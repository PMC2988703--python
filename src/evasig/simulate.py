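"""Synthetic expression data with a planted stage-associated overexpression block.

The generator emulates the statistical structure the discovery pipeline
targets: a probes x samples log2 intensity matrix in which a block of
signature probes is coordinately overexpressed in a subset ("carriers") of
the high-stage samples and in none of the low-stage samples.  Optionally the
block shares a common latent factor in carriers (so a designated proxy probe
is informative about the rest of the block), and an XOR logic-gate triple
(A, B, T) is planted in which T is elevated exactly when one of A, B is
elevated and the other is not — a pattern with near-zero marginal association
of either gate input with T but ~1 bit of joint association.

A matched "normal control" matrix applies the same marginal overexpression to
the same probes but independently per probe and sample, so block probes are
marginally similar yet mutually uncorrelated — the signature exists gene by
gene but is not coordinated, as in non-cancerous tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datasets import ExpressionDataset, PhenotypeVector

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset", "generate_normal_control", "generate_xor_triple"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-signature simulation.

    All intensities are on the log2 scale.  ``signature_shift`` is the mean
    log2 overexpression of the planted block in carrier samples;
    ``frac_signature_carriers`` is the fraction of *high-stage* samples that
    carry the block.  ``block_latent_sd`` sets the standard deviation of the
    latent factor shared by block probes within carriers (only used when
    ``include_proxy`` is set); with the default noise level it yields a
    within-block carrier correlation of about 0.2.  The gate triple uses its
    own, well-separated shift (``synergy_shift`` with ``synergy_noise_sd``) so
    that each gate state is unambiguous and the planted joint information is
    close to 1 bit by construction.

    ``layout_seed`` optionally decouples the layout (which probes are planted,
    which samples are high-stage/carriers) from the noise seed, so several
    independently-noised cohorts can share the same planted truth for
    cross-dataset intersection experiments.  When ``None`` the layout is drawn
    from the main ``seed`` stream.
    """

    n_probes: int = 1000
    n_samples: int = 300
    frac_high_stage: float = 5 / 6
    n_signature_probes: int = 20
    frac_signature_carriers: float = 0.4
    signature_shift: float = 2.0
    baseline_mean: float = 6.0
    noise_sd: float = 1.0
    block_latent_sd: float = 0.5
    include_proxy: bool = True
    include_synergy_triple: bool = False
    synergy_shift: float = 4.0
    synergy_noise_sd: float = 0.25
    seed: int = 0
    layout_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_samples < 1:
            raise ValueError("n_probes and n_samples must be positive")
        if not (0 < self.frac_high_stage < 1):
            raise ValueError("frac_high_stage must be in (0,1)")
        if not (0 < self.frac_signature_carriers < 1):
            raise ValueError("frac_signature_carriers must be in (0,1)")
        if not (0 < self.n_signature_probes < self.n_probes):
            raise ValueError("require 0 < n_signature_probes < n_probes")
        if self.noise_sd <= 0 or self.synergy_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.block_latent_sd < 0:
            raise ValueError("block_latent_sd must be nonnegative")

    @property
    def n_high(self) -> int:
        return round(self.frac_high_stage * self.n_samples)

    @property
    def n_carriers(self) -> int:
        return round(self.frac_signature_carriers * self.n_high)


@dataclass
class SyntheticDataset:
    """A planted dataset plus the ground truth needed to score recovery."""

    expression: ExpressionDataset
    phenotype: PhenotypeVector
    truth: set[str]
    carrier_samples: set[str]
    proxy_probe: Optional[str] = None
    synergy_triple: Optional[tuple[str, str, str]] = None  # (A, B, target)


@dataclass
class _Layout:
    high_idx: np.ndarray
    carrier_idx: np.ndarray
    planted_idx: np.ndarray
    row_order: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]


def _layout(config: SimulationConfig, rng: np.random.Generator) -> _Layout:
    """Sample/probe layout shared by the cancer and control generators.

    Drawn first with an identical stream so a control matrix generated from
    the same seed places the planted probes at the same identifiers.
    """
    n, p = config.n_samples, config.n_probes
    n_high = config.n_high
    if n_high == 0 or n_high == n:
        raise ValueError("frac_high_stage leaves a stage class empty at this n_samples")
    if config.n_carriers == 0:
        raise ValueError("carrier count rounds to zero; increase frac_signature_carriers or n_samples")
    high_idx = np.sort(rng.choice(n, size=n_high, replace=False))
    carrier_idx = np.sort(rng.choice(high_idx, size=config.n_carriers, replace=False))
    planted_idx = np.sort(rng.choice(p, size=config.n_signature_probes, replace=False))
    n_rows = p + (3 if config.include_synergy_triple else 0)
    row_order = rng.permutation(n_rows)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    probe_ids = [f"P{i + 1:06d}" for i in range(n_rows)]
    return _Layout(high_idx, carrier_idx, planted_idx, row_order, sample_ids, probe_ids)


def generate_xor_triple(
    n_samples: int,
    shift: float = 4.0,
    noise_sd: float = 0.25,
    baseline_mean: float = 6.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gate probes (A, B, T): T is elevated iff exactly one of A, B is elevated.

    The elevated/baseline states come from median-thresholded latent Gaussians,
    so each state occurs in half the samples; with the default well-separated
    shift the triple carries close to 1 bit of purely synergistic information
    about T and essentially none marginally.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    z_a = rng.normal(size=n_samples)
    z_b = rng.normal(size=n_samples)
    state_a = z_a > np.median(z_a)
    state_b = z_b > np.median(z_b)
    a = baseline_mean + shift * state_a + rng.normal(0, noise_sd, n_samples)
    b = baseline_mean + shift * state_b + rng.normal(0, noise_sd, n_samples)
    t = baseline_mean + shift * (state_a ^ state_b) + rng.normal(0, noise_sd, n_samples)
    return a, b, t


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one planted cancer-like dataset.

    Baseline expression is i.i.d. Normal(baseline_mean, noise_sd) per cell.
    Planted probes gain ``signature_shift`` (plus a shared latent factor when
    ``include_proxy``) in carrier samples only; carriers are a random subset
    of the high-stage samples, so low-stage samples never show the block.
    Identical config and seed give a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    lay = _layout(config, rng if config.layout_seed is None else np.random.default_rng(config.layout_seed))
    n, p = config.n_samples, config.n_probes

    X = rng.normal(config.baseline_mean, config.noise_sd, size=(p, n))
    X[np.ix_(lay.planted_idx, lay.carrier_idx)] += config.signature_shift
    if config.include_proxy and config.block_latent_sd > 0:
        latent = rng.normal(0.0, config.block_latent_sd, size=lay.carrier_idx.size)
        X[np.ix_(lay.planted_idx, lay.carrier_idx)] += latent[None, :]

    rows = [X]
    triple_rows: Optional[np.ndarray] = None
    if config.include_synergy_triple:
        a, b, t = generate_xor_triple(
            n, config.synergy_shift, config.synergy_noise_sd, config.baseline_mean, rng=rng
        )
        rows.append(np.vstack([a, b, t]))
        triple_rows = np.array([p, p + 1, p + 2])
    full = np.vstack(rows)[lay.row_order]

    inv = np.empty_like(lay.row_order)
    inv[lay.row_order] = np.arange(lay.row_order.size)
    truth = {lay.probe_ids[inv[i]] for i in lay.planted_idx}
    proxy = lay.probe_ids[inv[lay.planted_idx[0]]] if config.include_proxy else None
    triple = (
        tuple(lay.probe_ids[inv[i]] for i in triple_rows) if triple_rows is not None else None
    )

    high = np.zeros(n, dtype=bool)
    high[lay.high_idx] = True
    expr = ExpressionDataset(lay.probe_ids, lay.sample_ids, full)
    phen = PhenotypeVector(lay.sample_ids, high)
    return SyntheticDataset(
        expression=expr,
        phenotype=phen,
        truth=truth,
        carrier_samples={lay.sample_ids[i] for i in lay.carrier_idx},
        proxy_probe=proxy,
        synergy_triple=triple,  # type: ignore[arg-type]
    )


def generate_normal_control(config: SimulationConfig) -> ExpressionDataset:
    """Matched control matrix: same marginal shifts, no shared carrier set.

    Each planted probe is shifted independently per sample with probability
    ``n_carriers / n_samples`` (the carrier rate of the cancer matrix), so the
    planted probes match the cancer matrix marginally but are mutually
    uncorrelated.  The probe layout matches ``generate_dataset`` for the same
    seed, so planted identifiers correspond across the pair.
    """
    rng = np.random.default_rng(config.seed)
    lay = _layout(config, rng if config.layout_seed is None else np.random.default_rng(config.layout_seed))
    n, p = config.n_samples, config.n_probes

    X = rng.normal(config.baseline_mean, config.noise_sd, size=(p, n))
    rate = config.n_carriers / n
    shifted = rng.random(size=(lay.planted_idx.size, n)) < rate
    X[lay.planted_idx] += config.signature_shift * shifted

    rows = [X]
    if config.include_synergy_triple:
        rows.append(rng.normal(config.baseline_mean, config.noise_sd, size=(3, n)))
    full = np.vstack(rows)[lay.row_order]
    return ExpressionDataset(lay.probe_ids, lay.sample_ids, full)
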