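"""Vectorized fitness kernels for the evolutionary fit.

The differential-evolution stage evaluates whole candidate populations at
once.  For a batch of free-parameter vectors these kernels assemble the
per-condition model matrices, compute the physiological equilibrium through
the scalar-quadratic reduction (one stacked 6x6 solve per condition), take
the leading Jacobian eigenvalue, and emit the fitness figure matrix.  The
same kernels expose a smooth residual vector used by the trust-region
refinement stage.
"""

from __future__ import annotations

import numpy as np

from .model import AREA_INDEX, AREAS, BETA_KEY, COUPLING_SIGNS, alpha_key, ext_key

_S_IDX = AREA_INDEX["SNcVTA"]
_L_IDX = AREA_INDEX["LC"]
_N = len(AREAS)

#: weight turning a 1/s eigenvalue excess into a refinement residual
_STAB_RESIDUAL_WEIGHT = 1e-2

#: interior floor (Hz) used by the refinement box hinges: fitted equilibria
#: keep every area minimally active, so small perturbations cannot push a
#: resting area through zero (a hard stop for the simulator)
_INTERIOR_FLOOR_HZ = 0.1


class ConditionKernel:
    """Maps batches of free-parameter vectors to equilibrium figures for one
    condition.

    ``spec`` resolves every rate-parameter key either to a column of the
    search vector (``("x", col)``) or to a frozen value (``("c", value)``).
    """

    def __init__(self, tau_s: np.ndarray, spec: dict[str, tuple]):
        self.tau = np.asarray(tau_s, dtype=float)
        self.diag = -1.0 / self.tau

        e_rows, e_cols, e_signs, e_isx, e_col, e_val = [], [], [], [], [], []
        for (t, s), sign in COUPLING_SIGNS.items():
            kind, ref = spec[alpha_key(t, s)]
            e_rows.append(AREA_INDEX[t])
            e_cols.append(AREA_INDEX[s])
            e_signs.append(float(sign))
            e_isx.append(kind == "x")
            e_col.append(int(ref) if kind == "x" else 0)
            e_val.append(float(ref) if kind == "c" else 0.0)
        self.e_rows = np.array(e_rows)
        self.e_cols = np.array(e_cols)
        self.e_signs = np.array(e_signs)
        self.e_isx = np.array(e_isx)
        self.e_col = np.array(e_col)
        self.e_val = np.array(e_val)

        b_isx, b_col, b_val = [], [], []
        for a in AREAS:
            kind, ref = spec[ext_key(a)]
            b_isx.append(kind == "x")
            b_col.append(int(ref) if kind == "x" else 0)
            b_val.append(float(ref) if kind == "c" else 0.0)
        self.b_isx = np.array(b_isx)
        self.b_col = np.array(b_col)
        self.b_val = np.array(b_val)

        kind, ref = spec[BETA_KEY]
        self.beta_isx = kind == "x"
        self.beta_ref = int(ref) if kind == "x" else float(ref)

    def evaluate(self, X: np.ndarray) -> dict:
        """Equilibrium, leading eigenvalue and validity for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        P = X.shape[0]

        A = np.zeros((P, _N, _N))
        A[:, np.arange(_N), np.arange(_N)] = self.diag
        vals = np.where(self.e_isx, X[:, self.e_col], self.e_val)
        A[:, self.e_rows, self.e_cols] = self.e_signs * vals
        b = np.where(self.b_isx, X[:, self.b_col], self.b_val)
        beta = X[:, self.beta_ref] if self.beta_isx else np.full(P, self.beta_ref)

        rhs = np.zeros((P, _N, 2))
        rhs[:, :, 0] = -b
        rhs[:, _S_IDX, 1] = -1.0
        det = np.linalg.det(A)
        ok = np.isfinite(det) & (np.abs(det) > 1e-30)
        A_safe = np.where(ok[:, None, None], A, -np.eye(_N))
        sol = np.linalg.solve(A_safe, rhs)
        u, w = sol[:, :, 0], sol[:, :, 1]

        q = beta * w[:, _L_IDX]
        uj = u[:, _L_IDX]
        disc = 1.0 - 4.0 * q * uj
        ok = ok & (disc >= 0.0) & np.all(np.isfinite(u), axis=1) & np.all(np.isfinite(w), axis=1)
        sq = np.sqrt(np.clip(disc, 0.0, None))
        L = 2.0 * uj / (1.0 + sq)
        y = u + (beta * L * L)[:, None] * w

        J = A.copy()
        J[:, _S_IDX, _L_IDX] += 2.0 * beta * L
        with np.errstate(all="ignore"):
            eig = np.linalg.eigvals(np.where(np.isfinite(J).all(axis=(1, 2))[:, None, None], J, -np.eye(_N)))
        lam = eig.real.max(axis=1)
        ok = ok & np.all(np.isfinite(y), axis=1)
        return {
            "y": y, "lam": lam, "ok": ok, "disc": disc,
            "u": u, "w": w, "q": q, "beta": beta,
        }


class ConditionComponents:
    """Fitness figures of one condition, evaluated on batches.

    ``stim_constraints`` lists (column, reference drive) pairs for treatment
    modes: the figure 1/(1 + max(0, S_ref - x[col])) forces stimulation over
    inhibition.
    """

    def __init__(
        self,
        kernel: ConditionKernel,
        point_targets: dict[str, float],
        range_targets: dict[str, tuple[float, float]],
        *,
        fmax: float,
        margin: float,
        stim_constraints: list[tuple[int, float]] | None = None,
    ):
        self.kernel = kernel
        self.point_idx = np.array([AREA_INDEX[a] for a in point_targets], dtype=int)
        self.point_val = np.array(list(point_targets.values()), dtype=float)
        self.range_idx = np.array([AREA_INDEX[a] for a in range_targets], dtype=int)
        self.range_lo = np.array([r[0] for r in range_targets.values()], dtype=float)
        self.range_hi = np.array([r[1] for r in range_targets.values()], dtype=float)
        self.fmax = fmax
        self.margin = margin
        self.stim = list(stim_constraints or [])
        self.names = (
            [f"err:{a}" for a in point_targets]
            + [f"range:{a}" for a in range_targets]
            + [f"stim:{col}" for col, _ in self.stim]
            + ["stability", "physical"]
        )

    def matrix(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P, n_figures) figure matrix and a graded guidance penalty."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ev = self.kernel.evaluate(X)
        y, lam, ok = ev["y"], ev["lam"], ev["ok"]
        y_safe = np.where(np.isfinite(y), y, 0.0)
        cols = []
        if self.point_idx.size:
            r = (y_safe[:, self.point_idx] - self.point_val) / self.point_val
            cols.append(np.where(ok[:, None], 1.0 / (1.0 + r * r), 0.0))
        if self.range_idx.size:
            v = y_safe[:, self.range_idx]
            r = np.where(
                v < self.range_lo,
                (self.range_lo - v) / self.range_lo,
                np.where(v > self.range_hi, (v - self.range_hi) / self.range_hi, 0.0),
            )
            cols.append(np.where(ok[:, None], 1.0 / (1.0 + r * r), 0.0))
        for col, ref in self.stim:
            gap = np.maximum(0.0, ref - X[:, col])
            cols.append((1.0 / (1.0 + gap))[:, None])
        pen = np.maximum(0.0, np.where(np.isfinite(lam), lam, np.inf) + self.margin)
        cols.append(np.where(ok, 1.0 / (1.0 + np.where(np.isfinite(pen), pen, 1e9)), 0.0)[:, None])
        inside = ok & (y_safe.min(axis=1) >= 0.0) & (y_safe.max(axis=1) <= self.fmax)
        cols.append(np.where(inside, 1.0, 0.0)[:, None])
        figures = np.hstack(cols)

        # graded guidance for the evolutionary stage only
        overflow = np.maximum(0.0, -y_safe).sum(axis=1) + np.maximum(0.0, y_safe - self.fmax).sum(axis=1) / self.fmax
        guide = np.where(ok, 0.0, 1.0 + np.sqrt(np.clip(-ev["disc"], 0.0, 1e6)))
        guide = guide + np.minimum(1.0, overflow)
        return figures, guide

    def residual_matrix(self, X: np.ndarray) -> np.ndarray:
        """Smooth residual rows for the trust-region refinement (batched).

        Members beyond the fold of the quadratic (no real equilibrium) are
        continued through the tangent root and charged an extra residual, so
        the refinement can climb back into the feasible region.  Box hinges
        use a small interior floor (1e-3 Hz) so refined states end strictly
        inside the physical box rather than on its boundary.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ev = self.kernel.evaluate(X)
        ok, disc, q, u, w, beta = (
            ev["ok"], ev["disc"], ev["q"], ev["u"], ev["w"], ev["beta"],
        )
        uL = u[:, _L_IDX]
        sq = np.sqrt(np.clip(disc, 0.0, None))
        with np.errstate(all="ignore"):
            L_fold = np.where(q != 0.0, 0.5 / np.where(q != 0.0, q, 1.0), uL)
        L = np.where(disc >= 0.0, 2.0 * uL / (1.0 + sq), L_fold)
        y = u + (beta * L * L)[:, None] * w
        y = np.where(np.isfinite(y), y, 1e3)
        lam = np.where(np.isfinite(ev["lam"]), ev["lam"], 1e3)

        cols = []
        if self.point_idx.size:
            cols.append((y[:, self.point_idx] - self.point_val) / self.point_val)
        if self.range_idx.size:
            v = y[:, self.range_idx]
            cols.append(np.where(
                v < self.range_lo,
                (self.range_lo - v) / self.range_lo,
                np.where(v > self.range_hi, (v - self.range_hi) / self.range_hi, 0.0),
            ))
        for col, ref in self.stim:
            cols.append(np.maximum(0.0, ref - X[:, col])[:, None])
        cols.append((_STAB_RESIDUAL_WEIGHT * np.maximum(0.0, lam + 2.0 * self.margin))[:, None])
        floor = _INTERIOR_FLOOR_HZ
        box = (
            np.maximum(0.0, floor - y).sum(axis=1)
            + np.maximum(0.0, y - (self.fmax - floor)).sum(axis=1) / self.fmax
        )
        cols.append(box[:, None])
        cols.append(np.sqrt(np.clip(-disc, 0.0, None))[:, None])
        out = np.hstack(cols)
        return np.where(np.isfinite(out), out, 1e6)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.residual_matrix(np.asarray(x, dtype=float)[None, :])[0]
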