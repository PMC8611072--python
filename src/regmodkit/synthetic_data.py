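"""Synthetic differentiation time courses with planted regulatory structure.

The generator emulates the statistical skeleton of a dense ex vivo
differentiation experiment: daily sampling over ``n_days`` days from
``n_donors`` donors, with chromatin accessibility (DHS density, count-like
scale) and gene expression (FPKM-like scale) matrices driven by a small set
of transcription-factor "modules".

Generative model
----------------
* Each module has a smooth activity curve over days: an early logistic
  ramp-down, interior transient bumps built as differences of two
  logistics, and late logistic ramp-ups.
* Each TF belongs to one module; its expression is the module curve
  rescaled to a TF-specific FPKM range plus Gaussian replicate noise.
* Each *changing* DHS carries 1-3 positive TF effects from one module; its
  per-sample signal is ``softplus(sum effect * TF expression)`` linearly
  rescaled to a DHS-specific count range, plus replicate noise.
  Non-changing DHSs are flat baselines plus noise.
* Each *changing* gene is a weighted sum of its planted enhancer DHSs
  (same module), rescaled to an FPKM range, plus noise.  Enhancers lie
  within ``link_window`` of the gene TSS; each gene also gets a same-module
  decoy DHS placed at 1.2-2x the window (correlated but out of range) and
  flat decoy DHSs inside the window.
* The motif table holds one hit per true (DHS, TF) effect plus
  Poisson(``decoy_motif_rate``) decoy hits for every (DHS, TF) pair.

Replicate noise is Gaussian with standard deviation ``noise_sd`` times the
feature's dynamic range (its baseline for flat features), so one knob sets
the signal-to-noise of the whole dataset.

All randomness flows from a single :class:`numpy.random.Generator`, so a
given seed reproduces the dataset bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_formats import GenomicInterval, MotifHitTable, TimeCourseMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "module_activity_curves",
    "generate_dataset",
    "score_recovery",
]


@dataclass
class SimulationConfig:
    """Conditions of the emulated differentiation time course."""

    n_days: int = 13
    n_donors: int = 3
    n_tf: int = 40
    n_modules: int = 5
    n_dhs: int = 2000
    n_genes: int = 300
    frac_changing_dhs: float = 0.3
    frac_changing_genes: float = 0.5
    noise_sd: float = 0.05
    effect_scale: float = 1.0
    decoy_motif_rate: float = 0.5
    link_window: int = 1_000_000
    dhs_width: int = 200
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_days": self.n_days,
            "n_donors": self.n_donors,
            "n_tf": self.n_tf,
            "n_modules": self.n_modules,
            "n_dhs": self.n_dhs,
            "n_genes": self.n_genes,
            "link_window": self.link_window,
            "dhs_width": self.dhs_width,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.frac_changing_dhs <= 1.0:
            raise ValueError("frac_changing_dhs must be in [0, 1]")
        if not 0.0 <= self.frac_changing_genes <= 1.0:
            raise ValueError("frac_changing_genes must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.decoy_motif_rate < 0:
            raise ValueError("decoy_motif_rate must be >= 0")
        if self.n_modules > self.n_tf:
            raise ValueError("need at least one TF per module")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for recovery scoring."""

    tf_module: pd.Series  # tf_name -> module (1..n_modules)
    tf_activity: pd.DataFrame  # tf_name x day noiseless expression
    dhs_changing: pd.Series  # dhs_id -> bool
    dhs_module: pd.Series  # changing dhs_id -> module
    tf_effects: pd.DataFrame  # columns dhs_id, tf_name, effect
    gene_changing: pd.Series  # gene_id -> bool (targets only, TF genes True)
    gene_links: pd.DataFrame  # columns gene_id, dhs_id, weight
    beyond_window_decoys: pd.DataFrame  # columns gene_id, dhs_id


@dataclass
class SyntheticDataset:
    dhs_matrix: TimeCourseMatrix
    gene_matrix: TimeCourseMatrix
    motif_hits: MotifHitTable
    intervals: list[GenomicInterval]
    annotation: pd.DataFrame  # gene_id, chrom, tss, strand
    truth: SyntheticTruth
    config: SimulationConfig

    def __iter__(self):
        yield from (
            self.dhs_matrix,
            self.gene_matrix,
            self.motif_hits,
            self.intervals,
            self.annotation,
            self.truth,
        )


def _logistic(t: np.ndarray, mid: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - mid) / scale))


def module_activity_curves(days: np.ndarray, n_modules: int) -> np.ndarray:
    """Noiseless per-day module activity curves, each normalized to [0, 1].

    Module 1 is an early ramp-down, the last module a late ramp-up;
    interior modules are transient bumps (difference of two logistics)
    with peaks spread across the course, mimicking sequential waves of
    regulatory activity.  Returns an (n_modules, n_days) array ordered by
    peak time.
    """
    t = np.asarray(days, dtype=float)
    T = t.max() - t.min()
    t0 = t.min()
    curves = []
    if n_modules == 5 and len(t) >= 8:
        # canonical five-wave layout for the default 13-day course
        curves.append(1.0 - _logistic(t, t0 + 0.25 * T, 0.10 * T))
        curves.append(_logistic(t, t0 + 0.18 * T, 0.06 * T) - _logistic(t, t0 + 0.48 * T, 0.06 * T))
        curves.append(_logistic(t, t0 + 0.43 * T, 0.06 * T) - _logistic(t, t0 + 0.73 * T, 0.06 * T))
        curves.append(_logistic(t, t0 + 0.58 * T, 0.10 * T))
        curves.append(_logistic(t, t0 + 0.83 * T, 0.07 * T))
    else:
        curves.append(1.0 - _logistic(t, t0 + 0.25 * T, 0.10 * T))
        if n_modules >= 2:
            mids = np.linspace(0.3, 0.7, max(n_modules - 2, 0))
            for m in mids:
                curves.append(
                    _logistic(t, t0 + (m - 0.15) * T, 0.06 * T)
                    - _logistic(t, t0 + (m + 0.15) * T, 0.06 * T)
                )
            curves.append(_logistic(t, t0 + 0.8 * T, 0.08 * T))
        curves = curves[:n_modules]
    out = np.vstack(curves)
    lo = out.min(axis=1, keepdims=True)
    hi = out.max(axis=1, keepdims=True)
    return (out - lo) / np.where(hi - lo > 0, hi - lo, 1.0)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_rescale(
    per_sample: np.ndarray, per_day_clean: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Softplus then linear map so the *noiseless* daily curve spans [lo, hi].

    Returns (rescaled per-sample signal, rescaled noiseless daily curve).
    The map is anchored on the noiseless curve so replicate noise does not
    shift the target range.
    """
    s = softplus(per_sample)
    s0 = softplus(per_day_clean)
    span = s0.max() - s0.min()
    if span <= 0:
        return np.full_like(s, lo), np.full_like(s0, lo)
    a = (hi - lo) / span
    return lo + a * (s - s0.min()), lo + a * (s0 - s0.min())


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset plus its truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.arange(config.n_days)
    donors = [f"d{j+1}" for j in range(config.n_donors)]
    sample_rows = [
        (f"day{d:02d}_{donor}", donor, int(d)) for d in days for donor in donors
    ]
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "donor", "day"]
    ).set_index("sample_id")
    sample_days = samples["day"].to_numpy()
    n_samples = len(samples)

    # --- TF expression ----------------------------------------------------
    curves = module_activity_curves(days, config.n_modules)
    tf_names = [f"TF{i+1:03d}" for i in range(config.n_tf)]
    tf_module = np.sort(np.arange(config.n_tf) % config.n_modules) + 1
    tf_expr = np.empty((config.n_tf, n_samples))
    tf_clean = np.empty((config.n_tf, config.n_days))
    for i in range(config.n_tf):
        lo = rng.uniform(0.5, 2.0)
        hi = rng.uniform(8.0, 30.0)
        curve = lo + (hi - lo) * curves[tf_module[i] - 1]
        tf_clean[i] = curve
        noise = rng.normal(0.0, config.noise_sd * (hi - lo), size=n_samples)
        tf_expr[i] = np.clip(curve[sample_days] + noise, 0.0, None)

    # --- feature allocation ----------------------------------------------
    n_changing_dhs = int(round(config.n_dhs * config.frac_changing_dhs))
    n_changing_genes = int(round(config.n_genes * config.frac_changing_genes))
    n_changing_genes = min(n_changing_genes, n_changing_dhs) if n_changing_dhs else 0

    dhs_ids = [f"dhs{i+1:05d}" for i in range(config.n_dhs)]
    gene_ids = [f"gene{i+1:04d}" for i in range(config.n_genes)]

    gene_module = np.zeros(config.n_genes, dtype=int)
    gene_module[:n_changing_genes] = (np.arange(n_changing_genes) % config.n_modules) + 1

    # plant enhancers: every changing gene gets one, then a second while
    # budget allows, then one beyond-window decoy per gene while budget allows
    enh_of_gene: dict[int, list[int]] = {g: [] for g in range(n_changing_genes)}
    decoy_of_gene: dict[int, int] = {}
    next_dhs = 0
    for g in range(n_changing_genes):
        enh_of_gene[g].append(next_dhs)
        next_dhs += 1
    for g in range(n_changing_genes):
        if next_dhs >= n_changing_dhs:
            break
        if rng.random() < 0.4:
            enh_of_gene[g].append(next_dhs)
            next_dhs += 1
    for g in range(n_changing_genes):
        if next_dhs >= n_changing_dhs:
            break
        decoy_of_gene[g] = next_dhs
        next_dhs += 1
    extra_changing = list(range(next_dhs, n_changing_dhs))

    dhs_changing = np.zeros(config.n_dhs, dtype=bool)
    dhs_changing[:n_changing_dhs] = True
    dhs_module = np.zeros(config.n_dhs, dtype=int)
    for g, idxs in enh_of_gene.items():
        for i in idxs:
            dhs_module[i] = gene_module[g]
    for g, i in decoy_of_gene.items():
        dhs_module[i] = gene_module[g]
    for j, i in enumerate(extra_changing):
        dhs_module[i] = (j % config.n_modules) + 1

    # --- changing DHS signals --------------------------------------------
    module_tfs = {m: np.flatnonzero(tf_module == m) for m in range(1, config.n_modules + 1)}
    dhs_values = np.empty((config.n_dhs, n_samples))
    dhs_clean = np.zeros((config.n_dhs, config.n_days))
    effects_rows: list[tuple[str, str, float]] = []
    for i in range(config.n_dhs):
        if not dhs_changing[i]:
            base = rng.uniform(5.0, 60.0)
            noise = rng.normal(0.0, config.noise_sd * base, size=n_samples)
            dhs_values[i] = np.clip(base + noise, 0.0, None)
            dhs_clean[i] = base
            continue
        m = dhs_module[i]
        pool = module_tfs[m]
        n_eff = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = rng.choice(pool, size=n_eff, replace=False)
        effs = config.effect_scale * rng.uniform(0.5, 1.5, size=n_eff)
        z = effs @ tf_expr[chosen]
        z0 = effs @ tf_clean[chosen]
        lo = rng.uniform(5.0, 15.0)
        hi = rng.uniform(40.0, 80.0)
        sig, sig0 = softplus_rescale(z, z0, lo, hi)
        noise = rng.normal(0.0, config.noise_sd * (hi - lo), size=n_samples)
        dhs_values[i] = np.clip(sig + noise, 0.0, None)
        dhs_clean[i] = sig0
        for t, e in zip(chosen, effs):
            effects_rows.append((dhs_ids[i], tf_names[t], float(e)))

    # --- gene expression ---------------------------------------------------
    gene_values = np.empty((config.n_genes, n_samples))
    link_rows: list[tuple[str, str, float]] = []
    for g in range(config.n_genes):
        if g >= n_changing_genes:
            base = rng.uniform(1.0, 20.0)
            noise = rng.normal(0.0, config.noise_sd * base, size=n_samples)
            gene_values[g] = np.clip(base + noise, 0.0, None)
            continue
        idxs = enh_of_gene[g]
        w = rng.uniform(0.5, 1.5, size=len(idxs))
        raw = w @ dhs_values[idxs]
        raw0 = w @ dhs_clean[idxs]
        glo = rng.uniform(1.0, 3.0)
        ghi = rng.uniform(10.0, 40.0)
        span = raw0.max() - raw0.min()
        a = (ghi - glo) / span if span > 0 else 0.0
        sig = glo + a * (raw - raw0.min())
        noise = rng.normal(0.0, config.noise_sd * (ghi - glo), size=n_samples)
        gene_values[g] = np.clip(sig + noise, 0.0, None)
        for i, wi in zip(idxs, w):
            link_rows.append((gene_ids[g], dhs_ids[i], float(wi)))

    # --- coordinates --------------------------------------------------------
    # one synthetic chromosome; one block per gene spaced far enough that a
    # 1.2-2x-window decoy of one gene cannot fall inside a neighbor's window
    chrom = "chrS"
    w = config.link_window
    span_block = int(4.2 * w)
    half = span_block // 2
    dhs_pos = np.zeros(config.n_dhs, dtype=int)
    placed = np.zeros(config.n_dhs, dtype=bool)
    tss = np.zeros(config.n_genes, dtype=int)
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    flat_pool = [i for i in range(config.n_dhs) if not dhs_changing[i]]
    rng.shuffle(flat_pool)
    flat_iter = iter(flat_pool)
    for g in range(config.n_genes):
        center = g * span_block + half
        tss[g] = center
        if g < n_changing_genes:
            for i in enh_of_gene[g]:
                off = int(rng.integers(2_000, int(0.8 * w)))
                off *= -1 if rng.random() < 0.5 else 1
                dhs_pos[i] = center + off
                placed[i] = True
            if g in decoy_of_gene:
                i = decoy_of_gene[g]
                off = int(rng.integers(int(1.2 * w), int(2.0 * w)))
                off *= -1 if rng.random() < 0.5 else 1
                dhs_pos[i] = center + off
                placed[i] = True
        # flat in-window decoys for every gene, while the flat pool lasts
        for _ in range(2):
            i = next(flat_iter, None)
            if i is None:
                break
            off = int(rng.integers(1_000, int(0.9 * w)))
            off *= -1 if rng.random() < 0.5 else 1
            dhs_pos[i] = center + off
            placed[i] = True
    # remaining features go to dedicated far blocks beyond any gene window
    tail = config.n_genes * span_block + 2 * span_block
    for i in range(config.n_dhs):
        if not placed[i]:
            dhs_pos[i] = tail
            tail += int(rng.integers(5_000, 50_000))
    # TF genes live in their own blocks past all DHSs
    tf_tss = tail + span_block + np.arange(config.n_tf) * span_block

    intervals = [
        GenomicInterval(
            chrom,
            int(dhs_pos[i] - config.dhs_width // 2),
            int(dhs_pos[i] + config.dhs_width // 2),
            dhs_ids[i],
        )
        for i in range(config.n_dhs)
    ]
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids + tf_names,
            "chrom": chrom,
            "tss": np.concatenate([tss, tf_tss]),
            "strand": np.concatenate([strand, np.full(config.n_tf, "+")]),
        }
    )

    # --- motif hits ---------------------------------------------------------
    decoys = rng.poisson(config.decoy_motif_rate, size=(config.n_dhs, config.n_tf))
    counts = decoys.astype(int)
    tf_index = {t: j for j, t in enumerate(tf_names)}
    dhs_index = {d: i for i, d in enumerate(dhs_ids)}
    for d, t, _ in effects_rows:
        counts[dhs_index[d], tf_index[t]] += 1
    nz = np.nonzero(counts)
    motif_table = pd.DataFrame(
        {
            "dhs_id": [dhs_ids[i] for i in nz[0]],
            "tf_name": [tf_names[j] for j in nz[1]],
            "hit_count": counts[nz],
        }
    ).sort_values(["dhs_id", "tf_name"], kind="stable").reset_index(drop=True)

    # --- assemble -----------------------------------------------------------
    dhs_matrix = TimeCourseMatrix(
        pd.DataFrame(dhs_values, index=dhs_ids, columns=samples.index), samples
    )
    all_gene_values = np.vstack([gene_values, tf_expr])
    gene_matrix = TimeCourseMatrix(
        pd.DataFrame(all_gene_values, index=gene_ids + tf_names, columns=samples.index),
        samples,
    )
    truth = SyntheticTruth(
        tf_module=pd.Series(tf_module, index=tf_names, name="module"),
        tf_activity=pd.DataFrame(tf_clean, index=tf_names, columns=days),
        dhs_changing=pd.Series(dhs_changing, index=dhs_ids, name="changing"),
        dhs_module=pd.Series(
            dhs_module[dhs_changing], index=np.array(dhs_ids)[dhs_changing], name="module"
        ),
        tf_effects=pd.DataFrame(effects_rows, columns=["dhs_id", "tf_name", "effect"]),
        gene_changing=pd.Series(
            np.concatenate(
                [np.arange(config.n_genes) < n_changing_genes, np.ones(config.n_tf, bool)]
            ),
            index=gene_ids + tf_names,
            name="changing",
        ),
        gene_links=pd.DataFrame(link_rows, columns=["gene_id", "dhs_id", "weight"]),
        beyond_window_decoys=pd.DataFrame(
            [(gene_ids[g], dhs_ids[i]) for g, i in sorted(decoy_of_gene.items())],
            columns=["gene_id", "dhs_id"],
        ),
    )
    return SyntheticDataset(
        dhs_matrix, gene_matrix, MotifHitTable(motif_table), intervals, annotation,
        truth, config,
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def _prf(true_set: set, called_set: set) -> dict:
    tp = len(true_set & called_set)
    precision = tp / len(called_set) if called_set else 0.0
    recall = tp / len(true_set) if true_set else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


def score_recovery(truth: SyntheticTruth, results: dict) -> dict:
    """Score downstream results against the planted truth.

    ``results`` may contain any of:

    * ``dhs_changing`` / ``gene_changing``: iterable of called feature ids;
    * ``links``: DataFrame with columns dhs_id, gene_id;
    * ``dhs_clusters``: Series dhs_id -> cluster label (changing DHSs);
    * ``tf_modules``: Series tf_name -> module label;
    * ``tf_effects``: DataFrame with columns dhs_id, tf_name, coefficient.

    Ids not present in the truth ledger raise an error listing them.
    """
    metrics: dict = {}
    if "dhs_changing" in results:
        called = set(results["dhs_changing"])
        _check_ids(called, set(truth.dhs_changing.index), "dhs")
        true = set(truth.dhs_changing.index[truth.dhs_changing])
        metrics["dhs_changing"] = _prf(true, called)
    if "gene_changing" in results:
        called = set(results["gene_changing"])
        _check_ids(called, set(truth.gene_changing.index), "gene")
        true = set(truth.gene_changing.index[truth.gene_changing])
        metrics["gene_changing"] = _prf(true, called)
    if "links" in results:
        df = results["links"]
        called = set(zip(df["gene_id"], df["dhs_id"]))
        _check_ids({g for g, _ in called}, set(truth.gene_changing.index), "gene")
        _check_ids({d for _, d in called}, set(truth.dhs_changing.index), "dhs")
        true = set(zip(truth.gene_links["gene_id"], truth.gene_links["dhs_id"]))
        metrics["links"] = _prf(true, called)
    if "dhs_clusters" in results:
        called = results["dhs_clusters"]
        _check_ids(set(called.index), set(truth.dhs_changing.index), "dhs")
        common = called.index.intersection(truth.dhs_module.index)
        metrics["cluster_ari"] = float(
            adjusted_rand_score(truth.dhs_module.loc[common], called.loc[common])
        )
    if "tf_modules" in results:
        called = results["tf_modules"]
        _check_ids(set(called.index), set(truth.tf_module.index), "tf")
        common = called.index.intersection(truth.tf_module.index)
        metrics["module_ari"] = float(
            adjusted_rand_score(truth.tf_module.loc[common], called.loc[common])
        )
    if "tf_effects" in results:
        df = results["tf_effects"]
        _check_ids(set(df["dhs_id"]), set(truth.dhs_changing.index), "dhs")
        merged = truth.tf_effects.merge(df, on=["dhs_id", "tf_name"], how="left")
        coef = merged["coefficient"].fillna(0.0)
        nonzero = coef != 0.0
        metrics["effect_recovery"] = float(nonzero.mean()) if len(merged) else 0.0
        if nonzero.any():
            metrics["sign_accuracy"] = float(
                (np.sign(coef[nonzero]) == np.sign(merged["effect"][nonzero])).mean()
            )
        else:
            metrics["sign_accuracy"] = float("nan")
    return metrics


def _check_ids(called: set, known: set, kind: str) -> None:
    unknown = sorted(called - known)
    if unknown:
        raise ValueError(f"unknown {kind} id(s) in results: {unknown[:10]}")
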