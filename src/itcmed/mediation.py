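"""Mass-univariate three-path mediation over grey-matter-density volumes.

Every in-mask voxel is tested as a mediator M of the group effect (X,
binary bvFTD indicator) on a scalar behavioural outcome Y via three OLS
regressions sharing any covariates:

    M = i1 + a*X          (path a: atrophy)
    Y = i2 + c'*X + b*M   (path b: structure-behaviour link; c': direct effect)
    Y = i3 + c*X          (path c: total effect)

The indirect effect is ab = a*b, and without covariates (or with the same
covariates everywhere) ab = c - c' exactly.  Inference is by percentile
bootstrap over participants: every replicate re-fits all paths at every
voxel, and the two-sided p for a statistic is 2*min(#{<=0}, #{>=0})/n_boot,
floored at 2/n_boot.  Significance is thresholded by Benjamini-Hochberg FDR
applied once to the pooled p-values of paths a, b and ab (3V values), and
mediating regions are read off a sign-constrained conjunction of the three
FDR masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label


class InvalidConstraintError(ValueError):
    """Sign constraints incompatible with ab = a*b."""


@dataclass(frozen=True)
class MediationConfig:
    n_boot: int = 10_000
    q: float = 0.05
    seed: int | None = 0
    pooling: str = "across_paths"  # or "per_path"
    min_cluster_size: int = 5
    chunk: int = 256  # bootstrap replicates processed per vectorized block


@dataclass
class MediationVoxelResult:
    a: float
    b: float
    ab: float
    c: float
    c_prime: float
    p_a: float = np.nan
    p_b: float = np.nan
    p_ab: float = np.nan


@dataclass
class MediationMaps:
    """Whole-brain mediation output: coefficient/p maps and masks share the
    input grid; voxels outside the analysis mask (or with zero variance)
    are NaN."""

    mask: np.ndarray
    coef: dict[str, np.ndarray]     # keys a, b, ab, c, c_prime
    p: dict[str, np.ndarray]        # keys a, b, ab
    fdr_masks: dict[str, np.ndarray]
    fdr_cutoff: float
    conjunction_masks: dict[str, np.ndarray]
    clusters: pd.DataFrame
    manifest: dict

    def save(self, out_dir, affine: np.ndarray | None = None) -> None:
        import json

        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4) if affine is None else affine
        for name, arr in {**{f"coef_{k}": v for k, v in self.coef.items()},
                          **{f"p_{k}": v for k, v in self.p.items()}}.items():
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine),
                     out_dir / f"{name}.nii.gz")
        for name, m in {**{f"fdr_{k}": v for k, v in self.fdr_masks.items()},
                        **{f"conj_{k}": v for k, v in self.conjunction_masks.items()},
                        "mask": self.mask}.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                     out_dir / f"{name}.nii.gz")
        self.clusters.to_csv(out_dir / "clusters.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


# ---------------------------------------------------------------------------
# vectorized weighted path fits


def _design(X: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Common design [1, X, covariates]; returns (Z, index of the X column)."""
    X = np.asarray(X, dtype=float).ravel()
    cols = [np.ones_like(X), X]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(X):
            C = C.T
        cols.extend(C.T)
    return np.column_stack(cols), 1


def _weighted_paths(W: np.ndarray, Z: np.ndarray, x_col: int,
                    M: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Paths a, b, ab, c for R weighted replicates at V voxels.

    ``W`` is an (R, n) matrix of non-negative resampling weights (counts);
    ``Z`` the shared (n, p) design; ``M`` (n, V) mediator values; ``Y`` (n,)
    the outcome.  Solves the weighted normal equations in closed form via
    block inversion.  Returns arrays of shape (R, V) (c is (R, 1)).
    Zero-residual-variance voxels yield NaN.
    """
    G = np.einsum("rn,np,nq->rpq", W, Z, Z)            # (R, p, p)
    P = np.linalg.inv(G)
    Zy = np.einsum("rn,np,n->rp", W, Z, Y)             # (R, p)
    A = np.einsum("rn,np,nv->rpv", W, Z, M)            # (R, p, V)
    Smm = W @ (M * M)                                   # (R, V)
    Smy = W @ (M * Y[:, None])                          # (R, V)
    PA = np.einsum("rpq,rqv->rpv", P, A)
    PZy = np.einsum("rpq,rq->rp", P, Zy)
    denom = Smm - np.einsum("rpv,rpv->rv", A, PA)       # residual SS of M | Z
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (Smy - np.einsum("rpv,rp->rv", A, PZy)) / denom
    bad = denom <= np.maximum(Smm, 1.0) * 1e-12
    b[bad] = np.nan
    a = PA[:, x_col, :]
    c = PZy[:, x_col][:, None]
    return {"a": a, "b": b, "ab": a * b, "c": c}


def fit_voxel_mediation(X_group, M_voxel_gmd, Y_outcome,
                        covariates=None) -> MediationVoxelResult:
    """Point estimates of all five mediation coefficients at one voxel.

    ``c_prime`` comes from an explicit least-squares solve of
    Y ~ [1, X, M, cov]; without covariates ab = c - c_prime holds to
    numerical precision.
    """
    M = np.asarray(M_voxel_gmd, dtype=float).reshape(-1, 1)
    Y = np.asarray(Y_outcome, dtype=float)
    Z, x_col = _design(X_group, covariates)
    if len(Y) < 10:
        raise ValueError("need >= 10 participants")
    W = np.ones((1, len(Y)))
    paths = _weighted_paths(W, Z, x_col, M, Y)
    full = np.column_stack([Z, M])
    coef, *_ = np.linalg.lstsq(full, Y, rcond=None)
    return MediationVoxelResult(
        a=float(paths["a"][0, 0]), b=float(paths["b"][0, 0]),
        ab=float(paths["ab"][0, 0]), c=float(paths["c"][0, 0]),
        c_prime=float(coef[x_col]))


def _resample_counts(rng: np.random.Generator, n: int, n_boot: int,
                     group: np.ndarray, max_redraw: int = 100) -> np.ndarray:
    """Multinomial resampling-with-replacement counts; replicates that drop
    an entire group are redrawn (capped)."""
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
    g1 = group.astype(bool)
    for _ in range(max_redraw):
        bad = (W[:, g1].sum(axis=1) == 0) | (W[:, ~g1].sum(axis=1) == 0)
        if not bad.any():
            return W
        W[bad] = rng.multinomial(n, np.full(n, 1.0 / n), size=int(bad.sum()))
    raise RuntimeError("could not draw non-degenerate bootstrap replicates")


def bootstrap_mediation(X, M, Y, covariates=None, n_boot: int = 10_000,
                        seed: int | None = 0, chunk: int = 256,
                        ) -> dict[str, np.ndarray]:
    """Percentile-bootstrap two-sided p-values for paths a, b and ab.

    Participants are resampled with replacement; all paths are re-fit per
    replicate at every voxel.  p = 2*min(#{theta* <= 0}, #{theta* >= 0}) /
    n_boot, floored at 2/n_boot (zeros count on both sides).  The resampling
    plan is drawn once from the seed before any voxel work, so results do
    not depend on voxel ordering or chunking.
    """
    if n_boot < 1000:
        raise ValueError("need n_boot >= 1000")
    X = np.asarray(X, dtype=float).ravel()
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != len(X):
        M = M.T
    Y = np.asarray(Y, dtype=float)
    Z, x_col = _design(X, covariates)
    rng = np.random.default_rng(seed)
    W = _resample_counts(rng, len(X), n_boot, X)
    neg = {k: np.zeros(M.shape[1]) for k in ("a", "b", "ab")}
    pos = {k: np.zeros(M.shape[1]) for k in ("a", "b", "ab")}
    for start in range(0, n_boot, chunk):
        paths = _weighted_paths(W[start:start + chunk], Z, x_col, M, Y)
        for k in ("a", "b", "ab"):
            vals = paths[k]
            neg[k] += np.sum(vals <= 0, axis=0)
            pos[k] += np.sum(vals >= 0, axis=0)
    floor = 2.0 / n_boot
    out = {}
    for k in ("a", "b", "ab"):
        p = 2.0 * np.minimum(neg[k], pos[k]) / n_boot
        out[f"p_{k}"] = np.clip(p, floor, 1.0)
    return out


# ---------------------------------------------------------------------------
# FDR, conjunction, clusters


def bh_threshold(pvals: np.ndarray, q: float) -> float:
    """Benjamini-Hochberg step-up p cutoff (0.0 when nothing passes)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(p <= crit)[0]
    return float(p[passing[-1]]) if len(passing) else 0.0


def fdr_across_paths(p_maps: dict[str, np.ndarray], mask: np.ndarray,
                     q: float = 0.05, pooling: str = "across_paths",
                     ) -> tuple[dict[str, np.ndarray], float | dict[str, float]]:
    """BH-threshold the three path p-maps.

    ``across_paths`` (default) applies one BH procedure to the pooled in-mask
    p-values of paths a, b and ab (3V values) and uses the single resulting
    cutoff for all three; ``per_path`` thresholds each path separately.
    Returns (masks, realized voxel-level cutoff[s]).
    """
    if not mask.any():
        raise ValueError("empty mask")
    keys = ("a", "b", "ab")
    in_mask = {k: p_maps[k][mask] for k in keys}
    valid = {k: np.isfinite(in_mask[k]) for k in keys}
    masks = {}
    if pooling == "across_paths":
        pooled = np.concatenate([in_mask[k][valid[k]] for k in keys])
        cutoff = bh_threshold(pooled, q)
        for k in keys:
            sig = np.zeros_like(mask)
            sig[mask] = np.where(valid[k], in_mask[k] <= cutoff, False)
            masks[k] = sig
        return masks, cutoff
    if pooling == "per_path":
        cutoffs = {}
        for k in keys:
            cutoffs[k] = bh_threshold(in_mask[k][valid[k]], q)
            sig = np.zeros_like(mask)
            sig[mask] = np.where(valid[k], in_mask[k] <= cutoffs[k], False)
            masks[k] = sig
        return masks, cutoffs
    raise ValueError(f"unknown pooling mode {pooling!r}")


# sign conventions for the two task outcomes: atrophy (a<0) raising the
# discount rate needs b<0 (so ab>0); atrophy lowering LL-sensitivity needs
# b>0 (so ab<0)
SIGNS_DISCOUNT_RATE = {"a": -1, "b": -1, "ab": +1}
SIGNS_SENSITIVITY = {"a": -1, "b": +1, "ab": -1}


def conjunction(fdr_masks: dict[str, np.ndarray], sign_constraints: dict[str, int],
                coefficient_maps: dict[str, np.ndarray]) -> np.ndarray:
    """Voxels significant on paths a, b and ab with the requested signs.

    Signs are +1/-1 (0 = unconstrained) and must satisfy
    sign(a)*sign(b) = sign(ab) where all three are constrained.
    """
    sa, sb, sab = (sign_constraints.get(k, 0) for k in ("a", "b", "ab"))
    if sa and sb and sab and sa * sb != sab:
        raise InvalidConstraintError(
            f"sign constraints a:{sa} b:{sb} ab:{sab} violate ab = a*b")
    out = fdr_masks["a"] & fdr_masks["b"] & fdr_masks["ab"]
    for k in ("a", "b", "ab"):
        s = sign_constraints.get(k, 0)
        if s:
            with np.errstate(invalid="ignore"):
                out = out & (np.sign(np.nan_to_num(coefficient_maps[k])) == s)
    return out


def extract_clusters(mask: np.ndarray, coefficient_map: np.ndarray,
                     min_size: int = 5) -> pd.DataFrame:
    """26-connected components of a binary mask, size-filtered.

    Per cluster: label, size, peak-|coefficient| voxel index, peak
    coefficient, sign.  Sorted by size (descending).
    """
    labels = cc_label(mask.astype(np.uint8), connectivity=3)
    rows = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_size:
            continue
        coefs = coefficient_map[tuple(idx.T)]
        peak = idx[np.nanargmax(np.abs(coefs))]
        peak_val = coefficient_map[tuple(peak)]
        rows.append({
            "label": lab, "size": len(idx),
            "peak_x": int(peak[0]), "peak_y": int(peak[1]), "peak_z": int(peak[2]),
            "peak_coef": float(peak_val), "sign": int(np.sign(peak_val)),
        })
    df = pd.DataFrame(rows, columns=["label", "size", "peak_x", "peak_y",
                                     "peak_z", "peak_coef", "sign"])
    return df.sort_values("size", ascending=False, ignore_index=True) if len(df) else df


# ---------------------------------------------------------------------------
# whole-brain driver


def run_whole_brain(volumes: np.ndarray, mask: np.ndarray, X, Y,
                    covariates=None, config: MediationConfig | None = None,
                    sign_constraints: dict[str, int] | None = None,
                    ) -> MediationMaps:
    """Whole-brain mediation: per-voxel fits, bootstrap p-maps, pooled FDR,
    sign-constrained conjunction and cluster table.

    ``volumes`` is (n, *grid); participants with a missing outcome are
    listwise-dropped (recorded in the manifest).  Deterministic given
    ``config.seed``.
    """
    config = config or MediationConfig()
    sign_constraints = sign_constraints or SIGNS_DISCOUNT_RATE
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volumes.shape[1:] != mask.shape:
        raise ValueError(f"volume grid {volumes.shape[1:]} != mask grid {mask.shape}")
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    keep = np.isfinite(Y) & np.isfinite(X)
    dropped = int((~keep).sum())
    X, Y, volumes = X[keep], Y[keep], volumes[keep]
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(keep):
            cov = cov.T
        cov = cov[keep]

    M = volumes[:, mask]                                  # (n, V)
    Z, x_col = _design(X, cov)
    point = _weighted_paths(np.ones((1, len(X))), Z, x_col, M, Y)
    # explicit full solve for c' at every voxel (c' = c - ab must emerge, not
    # be assumed)
    V = M.shape[1]
    p_dim = Z.shape[1] + 1
    F = np.empty((V, len(X), p_dim))
    F[:, :, :-1] = Z[None]
    F[:, :, -1] = M.T
    G = np.einsum("vnp,vnq->vpq", F, F)
    Gy = np.einsum("vnp,n->vp", F, Y)
    with np.errstate(all="ignore"):
        try:
            coefs = np.linalg.solve(G, Gy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coefs = np.stack([np.linalg.lstsq(G[v], Gy[v], rcond=None)[0]
                              for v in range(V)])
    c_prime_flat = coefs[:, x_col]
    invalid = ~np.isfinite(point["b"][0])
    c_prime_flat[invalid] = np.nan

    pvals = bootstrap_mediation(X, M, Y, covariates=cov, n_boot=config.n_boot,
                                seed=config.seed, chunk=config.chunk)

    def to_map(flat):
        out = np.full(mask.shape, np.nan)
        out[mask] = flat
        return out

    coef_maps = {
        "a": to_map(point["a"][0]), "b": to_map(point["b"][0]),
        "ab": to_map(point["ab"][0]),
        "c": to_map(np.full(V, point["c"][0, 0])),
        "c_prime": to_map(c_prime_flat),
    }
    p_maps = {k: to_map(np.where(invalid, np.nan, pvals[f"p_{k}"]))
              for k in ("a", "b", "ab")}
    fdr_masks, cutoff = fdr_across_paths(p_maps, mask, q=config.q,
                                         pooling=config.pooling)
    conj = conjunction(fdr_masks, sign_constraints, coef_maps)
    clusters = extract_clusters(conj, coef_maps["ab"], config.min_cluster_size)
    manifest = {
        "n_participants": int(len(X)), "n_dropped": dropped,
        "n_voxels": int(mask.sum()), "n_invalid_voxels": int(invalid.sum()),
        "n_boot": config.n_boot, "q": config.q, "seed": config.seed,
        "pooling": config.pooling, "fdr_cutoff": cutoff,
        "sign_constraints": sign_constraints,
        "min_cluster_size": config.min_cluster_size,
    }
    return MediationMaps(mask=mask, coef=coef_maps, p=p_maps,
                         fdr_masks=fdr_masks, fdr_cutoff=cutoff if
                         isinstance(cutoff, float) else float("nan"),
                         conjunction_masks={"primary": conj},
                         clusters=clusters, manifest=manifest)
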