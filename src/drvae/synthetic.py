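"""Seeded synthetic pharmacogenomic data with known ground truth.

The generator emulates the statistical structure the DrVAE model family
assumes, so every pipeline stage is testable without external downloads:

* a low-dimensional latent state ``z1 ~ N(0, I)`` per cell line;
* a linear latent drug effect ``z2 = z1 + W* z1 + b*``;
* a fixed decoder (random orthonormal-column linear map, optionally
  followed by a mild tanh nonlinearity) from latent to gene space, shared
  by pre- and post-treatment states, plus i.i.d. per-gene noise;
* matched case-control pairs sharing batch/bead identifiers, with
  replicate vehicle controls scattered around each control profile;
* binary response labels drawn from a logistic rule on ``[z1, z2 - z1]``;
* continuous sensitivity (AAC) produced as a monotone transform of the
  logistic score, so waterfall binarization recovers the labels when the
  label signal is strong.

Everything is reproducible from ``SyntheticConfig.seed``; datasets
round-trip through the text formats used by the preprocessing module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gaussian import ValidationError
from .models import Batch
from .preprocess import PerturbationPair


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a small but realistic cohort.

    ``n_genes`` scales to 973 (the landmark-gene count shared by the real
    perturbation and viability sources) but defaults to 100 for speed.
    ``effect_scale`` multiplies the drawn ``W*, b*`` and is, together with
    ``replicate_sd``, the handle on the effect-to-replicate variance ratio.
    """

    n_genes: int = 100
    latent_dim_true: int = 5
    n_cell_lines_pairs: int = 8        # perturbation-source cell lines
    pairs_per_cell_line: int = 2
    n_singletons: int = 60             # viability-source cell lines
    replicates_per_control: int = 3
    effect_scale: float = 1.0
    label_scale: float = 3.0           # gain of the logistic label rule
    label_rule: str = "both"           # which blocks of [z1, z2-z1] carry
                                       # label weight: both|difference|baseline
    noise_sd_gene: float = 0.1
    replicate_sd: float = 0.1
    batch_count: int = 4
    decoder_gain: float = 0.2          # tanh gain; 0 = purely linear decoder
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.latent_dim_true, self.n_cell_lines_pairs,
               self.n_singletons, self.replicates_per_control,
               self.batch_count, self.pairs_per_cell_line) < 1:
            raise ValidationError("all counts must be positive")
        if self.noise_sd_gene < 0 or self.replicate_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.latent_dim_true > self.n_genes:
            raise ValidationError("latent_dim_true cannot exceed n_genes")
        if self.label_rule not in ("both", "difference", "baseline"):
            raise ValidationError(f"unknown label_rule {self.label_rule!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with each dataset, for recovery tests."""

    z1_pairs: np.ndarray        # (n_pairs, k) latent pre-treatment states
    z2_pairs: np.ndarray        # (n_pairs, k) == z1 + W* z1 + b* exactly
    z1_singles: np.ndarray
    labels_pairs: np.ndarray
    labels_singles: np.ndarray
    W_star: np.ndarray
    b_star: np.ndarray
    decoder_A: np.ndarray       # (k, G) orthonormal-row linear map
    decoder_c: np.ndarray
    decoder_gain: float
    label_weights: np.ndarray   # logistic weights on [z1, z2 - z1]
    label_score_pairs: np.ndarray = None    # P(y=1) per pair
    label_score_singles: np.ndarray = None
    realized_ervr: float = float("nan")
    x2_clean_pairs: np.ndarray = None   # decoder(z2) before gene noise


@dataclass
class SyntheticDataset:
    """In-memory dataset plus its truth; ``write`` emits the text formats."""

    pairs: list                       # PerturbationPair objects (labeled)
    replicate_controls: list          # list of (n_rep, G) arrays per pair
    singles_x1: np.ndarray
    singles_cell_lines: list
    singles_labels: np.ndarray
    sensitivity: pd.DataFrame         # drug_id, cell_line_id, aac
    truth: SyntheticTruth
    config: SyntheticConfig
    drug_id: str = "SYNDRUG"

    @property
    def pair_cell_lines(self) -> list:
        return sorted({p.cell_line_id for p in self.pairs})

    def to_batch(self, labeled_pairs: bool = True,
                 labeled_singles: bool = True) -> Batch:
        pairs = [(p.x1, p.x2, p.y if labeled_pairs else None)
                 for p in self.pairs]
        singles = [(x, int(y) if labeled_singles else None)
                   for x, y in zip(self.singles_x1, self.singles_labels)]
        return Batch.from_lists(pairs=pairs, singletons=singles,
                                n_genes=self.config.n_genes)

    def write(self, out_dir) -> None:
        """Emit expression TSVs, pair manifest CSV, sensitivity CSV and a
        truth archive (npz) under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genes = [f"g{i}" for i in range(self.config.n_genes)]

        rows, names, manifest = [], [], []
        for j, p in enumerate(self.pairs):
            cname, tname = f"ctrl_{j}", f"trt_{j}"
            rows += [p.x1, p.x2]
            names += [cname, tname]
            manifest.append({
                "drug_id": p.drug_id, "cell_line_id": p.cell_line_id,
                "control_sample": cname, "treated_sample": tname,
                "batch_id": p.batch_id, "bead_id": p.bead_id,
                "concentration": p.concentration, "duration_h": p.duration_h,
            })
            for r, rep in enumerate(self.replicate_controls[j]):
                rows.append(rep)
                names.append(f"ctrl_{j}_rep{r}")
        for i, x in enumerate(self.singles_x1):
            rows.append(x)
            names.append(f"single_{i}")
        expr = pd.DataFrame(np.asarray(rows), index=names, columns=genes)
        expr.to_csv(out / "expression.tsv", sep="\t")
        pd.DataFrame(manifest).to_csv(out / "pairs.csv", index=False)
        self.sensitivity.to_csv(out / "sensitivity.csv", index=False)

        t = self.truth
        np.savez(out / "truth.npz",
                 z1_pairs=t.z1_pairs, z2_pairs=t.z2_pairs,
                 z1_singles=t.z1_singles, labels_pairs=t.labels_pairs,
                 labels_singles=t.labels_singles, W_star=t.W_star,
                 b_star=t.b_star, decoder_A=t.decoder_A,
                 decoder_c=t.decoder_c, decoder_gain=t.decoder_gain,
                 label_weights=t.label_weights,
                 realized_ervr=t.realized_ervr)


def _orthonormal_rows(rng, k, G):
    m = rng.standard_normal((G, k))
    q, _ = np.linalg.qr(m)
    return q[:, :k].T        # (k, G) with orthonormal rows


def _decode_truth(z, A, c, gain):
    lin = z @ A + c
    if gain == 0.0:
        return lin
    return np.tanh(gain * lin) / gain


def _sigmoid(t):
    return 1.0 / (1.0 + np.exp(-t))


def generate(config: SyntheticConfig,
             decoder: Optional[tuple] = None) -> SyntheticDataset:
    """Draw one dataset.  ``decoder=(A, c)`` pins the gene map so that
    sweeps over other factors share one decoder."""
    rng = np.random.default_rng(config.seed)
    k, G = config.latent_dim_true, config.n_genes

    W = config.effect_scale * rng.standard_normal((k, k)) / np.sqrt(k)
    b = config.effect_scale * rng.standard_normal(k) / np.sqrt(k)
    if decoder is None:
        A = _orthonormal_rows(rng, k, G)
        c = 0.1 * rng.standard_normal(G)
    else:
        A, c = decoder
    w_label = config.label_scale * rng.standard_normal(2 * k) / np.sqrt(2 * k)
    if config.label_rule == "difference":
        w_label[:k] = 0.0
        w_label[k:] *= np.sqrt(2.0)    # keep the overall score variance scale
    elif config.label_rule == "baseline":
        w_label[k:] = 0.0
        w_label[:k] *= np.sqrt(2.0)

    n_pairs = config.n_cell_lines_pairs * config.pairs_per_cell_line
    z1p = rng.standard_normal((n_pairs, k))
    z2p = z1p + z1p @ W.T + b
    x1p = _decode_truth(z1p, A, c, config.decoder_gain)
    x2_clean = _decode_truth(z2p, A, c, config.decoder_gain)
    x1p_obs = x1p + config.noise_sd_gene * rng.standard_normal(x1p.shape)
    x2p_obs = x2_clean + config.noise_sd_gene * rng.standard_normal(x2_clean.shape)

    z1s = rng.standard_normal((config.n_singletons, k))
    z2s = z1s + z1s @ W.T + b
    x1s = _decode_truth(z1s, A, c, config.decoder_gain)
    x1s_obs = x1s + config.noise_sd_gene * rng.standard_normal(x1s.shape)

    def label_score(z1, z2):
        feats = np.concatenate([z1, z2 - z1], axis=1)
        return _sigmoid(feats @ w_label)

    score_p = label_score(z1p, z2p)
    score_s = label_score(z1s, z2s)
    y_p = (rng.random(n_pairs) < score_p).astype(int)
    y_s = (rng.random(config.n_singletons) < score_s).astype(int)

    pairs, rep_controls = [], []
    effects = []
    for i in range(n_pairs):
        cl = f"CLP{i // config.pairs_per_cell_line:03d}"
        batch = f"B{rng.integers(config.batch_count)}"
        bead = f"bead{i}"
        pairs.append(PerturbationPair(
            drug_id="SYNDRUG", cell_line_id=cl,
            x1=x1p_obs[i], x2=x2p_obs[i],
            batch_id=batch, bead_id=bead,
            concentration=1e-6, duration_h=6.0, y=int(y_p[i])))
        reps = x1p_obs[i] + config.replicate_sd * rng.standard_normal(
            (config.replicates_per_control, G))
        rep_controls.append(reps)
        effects.append(x2p_obs[i] - x1p_obs[i])

    from .evaluation import ervr
    if n_pairs >= 2 and config.replicates_per_control >= 2:
        realized = ervr(np.asarray(effects), rep_controls)
    else:
        realized = float("nan")

    single_cls = [f"CLS{i:03d}" for i in range(config.n_singletons)]
    # AAC: monotone in the logistic score, spread over [0.05, 0.95] so a
    # strong label signal produces a clear waterfall elbow
    aac_s = 0.05 + 0.9 * score_s
    aac_p_cl = {}
    for i in range(n_pairs):
        aac_p_cl.setdefault(pairs[i].cell_line_id, 0.05 + 0.9 * score_p[i])
    sens_rows = [{"drug_id": "SYNDRUG", "cell_line_id": cl, "aac": float(a)}
                 for cl, a in aac_p_cl.items()]
    sens_rows += [{"drug_id": "SYNDRUG", "cell_line_id": c, "aac": float(a)}
                  for c, a in zip(single_cls, aac_s)]

    truth = SyntheticTruth(
        z1_pairs=z1p, z2_pairs=z2p, z1_singles=z1s,
        labels_pairs=y_p, labels_singles=y_s,
        W_star=W, b_star=b, decoder_A=A, decoder_c=c,
        decoder_gain=config.decoder_gain, label_weights=w_label,
        label_score_pairs=score_p, label_score_singles=score_s,
        realized_ervr=float(realized), x2_clean_pairs=x2_clean)
    return SyntheticDataset(
        pairs=pairs, replicate_controls=rep_controls,
        singles_x1=x1s_obs, singles_cell_lines=single_cls,
        singles_labels=y_s,
        sensitivity=pd.DataFrame(sens_rows),
        truth=truth, config=config)


def make_sweep(effect_scales: Sequence[float],
               cell_line_counts: Sequence[int],
               base: SyntheticConfig,
               share_decoder: bool = True) -> list:
    """One dataset per (effect_scale, n_cell_lines_pairs) grid point.

    Seeds derive deterministically from ``base.seed``; when
    ``share_decoder`` is set, all grid points reuse one decoder map so the
    swept factors are isolated.  Returns a list of
    ``(config, SyntheticDataset)`` tuples in row-major grid order.
    """
    if not len(effect_scales) or not len(cell_line_counts):
        raise ValidationError("empty sweep grid")
    dec_rng = np.random.default_rng(np.random.SeedSequence(
        (base.seed, 0xDEC)).generate_state(1)[0])
    decoder = None
    if share_decoder:
        A = _orthonormal_rows(dec_rng, base.latent_dim_true, base.n_genes)
        c = 0.1 * dec_rng.standard_normal(base.n_genes)
        decoder = (A, c)
    out = []
    for i, es in enumerate(effect_scales):
        for j, ncl in enumerate(cell_line_counts):
            seed = int(np.random.SeedSequence(
                (base.seed, i, j)).generate_state(1)[0] % (2 ** 31))
            cfg = replace(base, effect_scale=float(es),
                          n_cell_lines_pairs=int(ncl), seed=seed)
            out.append((cfg, generate(cfg, decoder=decoder)))
    return out
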