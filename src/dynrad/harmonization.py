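"""Scanner (batch) harmonization of feature tables with reference-batch
ComBat.

Model: for feature *g*, subject *j* of batch *i*,

    y_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg,

estimated in a standardized space anchored on a chosen *reference* batch
(the location/scale used for standardization are the reference batch's own
mean and SD, so harmonization maps every other batch onto the reference
scanner and leaves reference-batch data untouched).  Per-batch location
(gamma) and scale (delta) estimates are stabilized by pooling information
across features with the *non-parametric* empirical-Bayes scheme of the
ComBat family: the prior is the empirical distribution of the per-feature
estimates, and the posterior mean is a likelihood-weighted average over the
other features' estimates (a deterministic Monte-Carlo integration over that
empirical prior).  No biological covariates enter the model.

Classical grand-mean-anchored ComBat is available behind ``anchor="grand"``
for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "fit_combat", "apply_combat"]

log = logging.getLogger("dynrad")


@dataclass
class CombatModel:
    """Fitted harmonization transform.

    ``loc``/``scale``: per-feature standardization parameters (reference
    batch's, or pooled for grand anchoring); ``gamma_star``/``delta_star``:
    EB-shrunk per-(batch, feature) location and scale effects in the
    standardized space; ``passthrough``: zero-variance features copied
    unchanged.
    """

    features: list
    reference_batch: str
    anchor: str
    loc: np.ndarray
    scale: np.ndarray
    gamma_star: dict
    delta_star: dict
    passthrough: list = field(default_factory=list)
    eb_mode: str = "nonparametric"

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "reference_batch": self.reference_batch,
            "anchor": self.anchor,
            "eb_mode": self.eb_mode,
            "loc": self.loc.tolist(),
            "scale": self.scale.tolist(),
            "gamma_star": {k: v.tolist() for k, v in self.gamma_star.items()},
            "delta_star": {k: v.tolist() for k, v in self.delta_star.items()},
            "passthrough": self.passthrough,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"], reference_batch=d["reference_batch"],
            anchor=d["anchor"], loc=np.asarray(d["loc"]),
            scale=np.asarray(d["scale"]),
            gamma_star={k: np.asarray(v) for k, v in d["gamma_star"].items()},
            delta_star={k: np.asarray(v) for k, v in d["delta_star"].items()},
            passthrough=d["passthrough"], eb_mode=d["eb_mode"],
        )


def _nonparametric_eb(Z: np.ndarray):
    """Non-parametric EB posterior estimates for one batch.

    ``Z``: (n_subjects, n_features) standardized data of the batch.  For
    each feature g the posterior weights over the other features' moment
    estimates (gamma_hat, delta2_hat) are the Gaussian likelihoods of
    feature g's data under those estimates; the weighted averages give
    (gamma*, delta2*).  Deterministic; O(p^2 n).
    """
    n, p = Z.shape
    g_hat = Z.mean(axis=0)                      # (p,)
    d2_hat = Z.var(axis=0, ddof=1)              # (p,)
    d2_hat = np.clip(d2_hat, 1e-12, None)
    if p == 1:
        return g_hat, d2_hat
    # log-likelihood of feature g's data under candidate (g', d2'):
    # sum_j log N(z_jg; g_hat[g'], d2_hat[g'])
    sum_z = Z.sum(axis=0)
    sum_z2 = (Z ** 2).sum(axis=0)
    # SSE(g, g') = sum_j (z_jg - g_hat[g'])^2
    sse = sum_z2[:, None] - 2.0 * sum_z[:, None] * g_hat[None, :] \
        + n * g_hat[None, :] ** 2
    loglik = -0.5 * (n * np.log(2.0 * np.pi * d2_hat)[None, :]
                     + sse / d2_hat[None, :])
    np.fill_diagonal(loglik, -np.inf)           # leave-one-out prior
    loglik -= loglik.max(axis=1, keepdims=True)
    w = np.exp(loglik)
    w /= w.sum(axis=1, keepdims=True)
    gamma_star = w @ g_hat
    delta2_star = w @ d2_hat
    return gamma_star, delta2_star


def fit_combat(features: pd.DataFrame, batch_ids, reference_batch: str,
               anchor: str = "reference",
               eb: str = "nonparametric") -> CombatModel:
    """Fit reference-anchored ComBat on a training feature table.

    ``features``: numeric subjects-x-features frame; ``batch_ids``: aligned
    batch labels.  Requires >= 2 batches with >= 3 subjects each and the
    reference batch present.  Zero-variance features are passed through
    unharmonized (logged).
    """
    if anchor not in ("reference", "grand"):
        raise ValueError("anchor must be 'reference' or 'grand'")
    batch_ids = pd.Series(np.asarray(batch_ids), index=features.index)
    batches = sorted(batch_ids.unique().tolist())
    if len(batches) < 2:
        raise ValueError("ComBat requires at least 2 batches")
    for b in batches:
        n_b = int((batch_ids == b).sum())
        if n_b < 3:
            raise ValueError(f"batch {b!r} has only {n_b} subjects (< 3)")
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} not in data")

    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    var_all = X.var(axis=0)
    passthrough = [names[g] for g in np.where(var_all == 0)[0]]
    if passthrough:
        log.warning("ComBat: zero-variance features passed through: %s",
                    passthrough)
    active = np.array([n not in passthrough for n in names])

    if anchor == "reference":
        ref_rows = (batch_ids == reference_batch).to_numpy()
        loc = X[ref_rows].mean(axis=0)
        scale = X[ref_rows].std(axis=0, ddof=1)
    else:
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
    scale = np.where(scale <= 0, 1.0, scale)

    Z = (X - loc) / scale
    gamma_star, delta_star = {}, {}
    for b in batches:
        rows = (batch_ids == b).to_numpy()
        Zb = Z[rows][:, active]
        if eb == "nonparametric":
            g_star, d2_star = _nonparametric_eb(Zb)
        else:
            g_star, d2_star = Zb.mean(axis=0), np.clip(
                Zb.var(axis=0, ddof=1), 1e-12, None)
        g_full = np.zeros(X.shape[1])
        d_full = np.ones(X.shape[1])
        g_full[active] = g_star
        d_full[active] = np.sqrt(d2_star)
        gamma_star[b] = g_full
        delta_star[b] = d_full

    return CombatModel(features=names, reference_batch=reference_batch,
                       anchor=anchor, loc=loc, scale=scale,
                       gamma_star=gamma_star, delta_star=delta_star,
                       passthrough=passthrough, eb_mode=eb)


def apply_combat(model: CombatModel, features: pd.DataFrame,
                 batch_ids) -> pd.DataFrame:
    """Apply a fitted ComBat transform; deterministic, reference rows pass
    unchanged, unseen batch ids raise."""
    if list(features.columns) != model.features:
        extra = set(features.columns) - set(model.features)
        missing = set(model.features) - set(features.columns)
        if extra or missing:
            raise ValueError(f"feature schema mismatch (extra={sorted(extra)},"
                             f" missing={sorted(missing)})")
        features = features[model.features]
    if features.empty:
        return features.copy()
    batch_ids = pd.Series(np.asarray(batch_ids), index=features.index)
    unseen = sorted(set(batch_ids.unique()) - set(model.gamma_star))
    if unseen:
        raise ValueError(f"batches not seen at fit time: {unseen}")

    X = features.to_numpy(dtype=float)
    out = X.copy()
    active = np.array([n not in model.passthrough for n in model.features])
    Z = (X - model.loc) / model.scale
    for b in model.gamma_star:
        rows = (batch_ids == b).to_numpy()
        if not rows.any():
            continue
        if model.anchor == "reference" and b == model.reference_batch:
            continue  # anchored: reference data is already on target
        adj = (Z[rows] - model.gamma_star[b]) / model.delta_star[b]
        adj = adj * model.scale + model.loc
        block = out[rows]
        block[:, active] = adj[:, active]
        out[rows] = block
    return pd.DataFrame(out, index=features.index, columns=model.features)
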