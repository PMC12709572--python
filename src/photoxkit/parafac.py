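"""Non-negative PARAFAC (CANDECOMP) decomposition of EEM cubes.

The model for a cube X (sample x excitation x emission) with F components is

    X_ijk ~= sum_f  score_if * ex_jf * em_kf,   all factors >= 0.

Fitting is alternating least squares with per-mode non-negative updates.
Excised (masked) cells are excluded from the objective via model imputation:
each sweep fills masked cells with the current model prediction and then
performs exact non-negative block updates, a majorize-minimize scheme that
guarantees the masked sum of squared errors never increases.

Diagnostics follow standard PARAFAC practice: core consistency (CORCONDIA)
for rank adequacy, split-half resampling with Tucker-congruence matching for
component stability, and congruence-based matching against a reference
component library for labelling.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment, nnls

from .spectra import EEMSpectrum
from .synthio import ComponentLibrary, stage_rng, tucker_congruence

__all__ = ["EEMCube", "Parafac", "ParafacResults", "excise_scatter", "split_half_validate"]


@dataclass
class EEMCube:
    """Stack of EEMs on shared grids, with a mask of excised cells."""

    sample_ids: list
    ex_grid: np.ndarray
    em_grid: np.ndarray
    tensor: np.ndarray  # (n_samples, n_ex, n_em)
    mask: np.ndarray  # True = excluded from the objective

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        expected = (len(self.sample_ids), self.ex_grid.size, self.em_grid.size)
        if self.tensor.shape != expected:
            raise ValueError(f"tensor shape {self.tensor.shape} != {expected}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.tensor.shape:
            raise ValueError("mask shape does not match tensor")
        if np.any(self.tensor[~self.mask] < 0):
            raise ValueError("unmasked EEM entries must be >= 0")

    @classmethod
    def from_eems(cls, eems: dict | list) -> "EEMCube":
        """Stack ``{sample_id: EEMSpectrum}`` (or id/EEM pairs) into a cube."""
        items = list(eems.items()) if isinstance(eems, dict) else list(eems)
        ids = [sid for sid, _ in items]
        first: EEMSpectrum = items[0][1]
        for _, e in items:
            if not (np.array_equal(e.ex_grid, first.ex_grid) and np.array_equal(e.em_grid, first.em_grid)):
                raise ValueError("all EEMs in a cube must share the same grids")
        tensor = np.stack([e.intensity for _, e in items])
        mask = np.stack([e.mask for _, e in items])
        return cls(ids, first.ex_grid.copy(), first.em_grid.copy(), tensor, mask)

    def n_samples(self) -> int:
        return len(self.sample_ids)


def excise_scatter(
    cube: EEMCube, first_order_halfwidth_nm: float = 15.0, second_order_halfwidth_nm: float = 15.0
) -> EEMCube:
    """Mask first- and second-order Rayleigh scatter ridges.

    Cells with |em - ex| <= hw1 or |em - 2*ex| <= hw2 are marked excised;
    intensities are left untouched (masked cells never enter the objective).
    """
    if first_order_halfwidth_nm < 0 or second_order_halfwidth_nm < 0:
        raise ValueError("halfwidths must be >= 0")
    ex = cube.ex_grid[:, None]
    em = cube.em_grid[None, :]
    ridge = (np.abs(em - ex) <= first_order_halfwidth_nm) | (
        np.abs(em - 2.0 * ex) <= second_order_halfwidth_nm
    )
    mask = cube.mask | ridge[None, :, :]
    return EEMCube(list(cube.sample_ids), cube.ex_grid.copy(), cube.em_grid.copy(),
                   cube.tensor.copy(), mask)


# ----------------------------------------------------------------- fitting


def _nnls_rows(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve min ||Z x - y||, x >= 0 for many rows sharing the Gram matrix.

    ``gram`` = Z^T Z (r x r), ``rhs`` rows are Z^T y.  Uses the Cholesky
    reduction so each row is an r x r NNLS problem.
    """
    r = gram.shape[0]
    ridge = 1e-12 * (np.trace(gram) / r if np.trace(gram) > 0 else 1.0)
    chol = cholesky(gram + ridge * np.eye(r), lower=False)
    b = solve_triangular(chol, rhs.T, trans="T")  # (r, n_rows)
    out = np.empty_like(rhs)
    for i in range(rhs.shape[0]):
        out[i], _ = nnls(chol, b[:, i])
    return out


def _model_tensor(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.einsum("if,jf,kf->ijk", a, b, c)


def _als_fit(
    tensor: np.ndarray,
    observed: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[list, list, bool]:
    n, j, k = tensor.shape
    a = rng.uniform(0.1, 1.0, (n, rank))
    b = rng.uniform(0.1, 1.0, (j, rank))
    c = rng.uniform(0.1, 1.0, (k, rank))
    model = _model_tensor(a, b, c)
    filled = np.where(observed, tensor, model)
    sse_history: list = []
    sst = float(np.sum(tensor[observed] ** 2))
    scale = max(sst, np.finfo(float).tiny)
    prev = math.inf
    converged = False
    for _ in range(max_iter):
        # mode updates on the imputed tensor (exact block minimization)
        zb = (c.T @ c) * (b.T @ b)
        a = _nnls_rows(zb, filled.reshape(n, j * k) @ _kr(b, c))
        za = (c.T @ c) * (a.T @ a)
        b = _nnls_rows(za, np.moveaxis(filled, 1, 0).reshape(j, n * k) @ _kr(a, c))
        zc = (b.T @ b) * (a.T @ a)
        c = _nnls_rows(zc, np.moveaxis(filled, 2, 0).reshape(k, n * j) @ _kr(a, b))
        model = _model_tensor(a, b, c)
        filled = np.where(observed, tensor, model)
        sse = float(np.sum((tensor[observed] - model[observed]) ** 2))
        sse_history.append(sse)
        # converged when the per-sweep improvement is negligible relative to
        # the data scale, or the fit is exact to machine precision
        if abs(prev - sse) < tol * scale or sse < 1e-15 * scale:
            converged = True
            break
        prev = sse
    return [a, b, c], sse_history, converged


def _kr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Khatri-Rao product with row index (i, j) ordered C-style."""
    r = x.shape[1]
    return (x[:, None, :] * y[None, :, :]).reshape(-1, r)


@dataclass
class ParafacResults:
    """Fitted PARAFAC factors, diagnostics, and component assignment."""

    cube: EEMCube
    n_components: int
    scores: np.ndarray  # (n_samples, F), scale absorbed here
    ex_loadings: np.ndarray  # (n_ex, F), unit maximum per column
    em_loadings: np.ndarray  # (n_em, F), unit maximum per column
    explained_variance: float
    sse_history: list
    n_iter: int
    converged: bool
    labels: list | None = None
    match_congruence: list | None = None

    def model_tensor(self) -> np.ndarray:
        return _model_tensor(self.scores, self.ex_loadings, self.em_loadings)

    def core_consistency(self) -> float:
        """CORCONDIA, percent: 100 for perfectly trilinear structure.

        Computed from the least-squares Tucker core of the (model-imputed)
        tensor against the superidentity.  NaN when a factor is degenerate.
        """
        a, b, c = self.scores, self.ex_loadings, self.em_loadings
        if min(np.linalg.norm(a, axis=0).min(), np.linalg.norm(b, axis=0).min(),
               np.linalg.norm(c, axis=0).min()) == 0:
            return math.nan
        filled = np.where(self.cube.mask, self.model_tensor(), self.cube.tensor)
        core = np.einsum("ai,bj,ck,ijk->abc", np.linalg.pinv(a), np.linalg.pinv(b),
                         np.linalg.pinv(c), filled)
        f = self.n_components
        ident = np.zeros((f, f, f))
        ident[np.arange(f), np.arange(f), np.arange(f)] = 1.0
        return 100.0 * (1.0 - float(np.sum((core - ident) ** 2)) / f)

    def component_fractions(self) -> pd.DataFrame:
        """Per-sample fractional component contributions (rows sum to 1)."""
        totals = self.scores.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.scores / totals[:, None]
        cols = self.labels if self.labels else [f"F{f + 1}" for f in range(self.n_components)]
        df = pd.DataFrame(frac, index=self.cube.sample_ids, columns=cols)
        df.index.name = "sample_id"
        df["undefined"] = totals <= 0
        return df

    def match_components(self, library: ComponentLibrary) -> list:
        """Label fitted components against a reference library.

        One-to-one assignment maximizing summed excitation + emission Tucker
        congruence (Hungarian algorithm); assignments with mean congruence
        below 0.8 are flagged with a warning.  Returns, per fitted component,
        the matched library index; also sets ``labels``.
        """
        if not (np.array_equal(library.ex_grid, self.cube.ex_grid)
                and np.array_equal(library.em_grid, self.cube.em_grid)):
            raise ValueError("library grids do not match the fitted cube")
        f = self.n_components
        cong = np.zeros((f, library.n_components))
        for i in range(f):
            for j in range(library.n_components):
                cong[i, j] = tucker_congruence(self.ex_loadings[:, i], library.ex_profiles[j]) + \
                    tucker_congruence(self.em_loadings[:, i], library.em_profiles[j])
        rows, cols = linear_sum_assignment(-cong)
        assignment = [int(c) for _, c in sorted(zip(rows, cols))]
        self.labels = [library.names[j] for j in assignment]
        self.match_congruence = [float(cong[i, j] / 2.0) for i, j in zip(rows, cols)]
        for i, (lab, cg) in enumerate(zip(self.labels, self.match_congruence)):
            if cg < 0.8:
                warnings.warn(f"component {i + 1} matched to {lab} with low congruence {cg:.3f}",
                              stacklevel=2)
        return assignment

    def summary(self) -> str:
        lines = [
            f"PARAFAC model: {self.n_components} components on "
            f"{self.cube.n_samples()} samples",
            f"  explained variance: {self.explained_variance:.6f}",
            f"  iterations: {self.n_iter} (converged={self.converged})",
        ]
        for i in range(self.n_components):
            lab = self.labels[i] if self.labels else f"F{i + 1}"
            ex_pk = self.cube.ex_grid[int(np.argmax(self.ex_loadings[:, i]))]
            em_pk = self.cube.em_grid[int(np.argmax(self.em_loadings[:, i]))]
            lines.append(f"  F{i + 1} [{lab}]: ex max {ex_pk:g} nm, em max {em_pk:g} nm")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "sample_ids": list(self.cube.sample_ids),
            "ex_grid": self.cube.ex_grid.tolist(),
            "em_grid": self.cube.em_grid.tolist(),
            "scores": self.scores.tolist(),
            "ex_loadings": self.ex_loadings.tolist(),
            "em_loadings": self.em_loadings.tolist(),
            "explained_variance": self.explained_variance,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "labels": self.labels,
            "match_congruence": self.match_congruence,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


class Parafac:
    """Non-negative PARAFAC model of an EEM cube (fit with ALS restarts)."""

    def __init__(self, cube: EEMCube, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if cube.n_samples() < n_components:
            raise ValueError("need at least as many samples as components")
        self.cube = cube
        self.n_components = n_components

    def fit(
        self,
        n_restarts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 2000,
        seed: int | None = None,
    ) -> ParafacResults:
        """Best-of-restarts masked non-negative ALS fit.

        Warns (and sets ``converged=False``) if the best restart exhausts
        ``max_iter`` without the relative SSE change dropping below ``tol``.
        """
        observed = ~self.cube.mask
        rng = stage_rng(0 if seed is None else seed, "parafac_fit")
        best = None
        for _ in range(n_restarts):
            factors, history, converged = _als_fit(
                self.cube.tensor, observed, self.n_components, rng, tol, max_iter
            )
            if best is None or history[-1] < best[1][-1]:
                best = (factors, history, converged)
        (a, b, c), history, converged = best
        if not converged:
            warnings.warn(
                f"PARAFAC did not reach tol={tol:g} within {max_iter} iterations", stacklevel=2
            )
        # normalize loadings to unit maximum, absorb scale into scores
        bmax = np.where(b.max(axis=0) > 0, b.max(axis=0), 1.0)
        cmax = np.where(c.max(axis=0) > 0, c.max(axis=0), 1.0)
        b = b / bmax
        c = c / cmax
        a = a * bmax * cmax
        # order components by descending explained sum of squares
        contrib = (a**2).sum(axis=0) * (b**2).sum(axis=0) * (c**2).sum(axis=0)
        order = np.argsort(-contrib)
        a, b, c = a[:, order], b[:, order], c[:, order]
        sst = float(np.sum(self.cube.tensor[observed] ** 2))
        ev = 1.0 - history[-1] / sst if sst > 0 else math.nan
        return ParafacResults(
            self.cube, self.n_components, a, b, c, ev, history, len(history), converged
        )


def split_half_validate(
    cube: EEMCube,
    n_components: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> float:
    """Split-half stability: minimum loading congruence between half fits.

    Samples are split into two random halves, each fitted independently;
    components are matched across halves by summed ex+em congruence and the
    minimum congruence over matched pairs and both spectral modes is
    returned (1 = perfectly stable components).
    """
    n = cube.n_samples()
    if n < 2 * n_components:
        raise ValueError("split-half validation needs >= 2 * n_components samples")
    rng = stage_rng(seed, "split_half")
    perm = rng.permutation(n)
    halves = [np.sort(perm[: n // 2]), np.sort(perm[n // 2:])]
    results = []
    for h, idx in enumerate(halves):
        sub = EEMCube(
            [cube.sample_ids[i] for i in idx], cube.ex_grid.copy(), cube.em_grid.copy(),
            cube.tensor[idx], cube.mask[idx],
        )
        results.append(
            Parafac(sub, n_components).fit(
                n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=int(rng.integers(2**31))
            )
        )
    r1, r2 = results
    f = n_components
    cong_sum = np.zeros((f, f))
    for i in range(f):
        for j in range(f):
            cong_sum[i, j] = tucker_congruence(r1.ex_loadings[:, i], r2.ex_loadings[:, j]) + \
                tucker_congruence(r1.em_loadings[:, i], r2.em_loadings[:, j])
    rows, cols = linear_sum_assignment(-cong_sum)
    min_cong = min(
        min(
            tucker_congruence(r1.ex_loadings[:, i], r2.ex_loadings[:, j]),
            tucker_congruence(r1.em_loadings[:, i], r2.em_loadings[:, j]),
        )
        for i, j in zip(rows, cols)
    )
    return float(min_cong)
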