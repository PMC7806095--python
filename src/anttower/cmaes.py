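"""Minimal (mu/mu_w, lambda)-CMA-ES in pure numpy.

Covariance Matrix Adaptation Evolution Strategy with the standard
machinery: weighted recombination of the best half of each population,
rank-1 and rank-mu covariance updates, and cumulative step-size
adaptation.  Ask/tell interface; minimization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CMAES"]


class CMAES:
    """Derivative-free stochastic minimizer.

    Parameters
    ----------
    x0:
        Initial distribution mean.
    sigma0:
        Initial global step size (coordinate-wise standard deviation).
    popsize:
        Candidates per iteration (default ``4 + floor(3 ln n)``).
    seed:
        Seed of the sampler.
    """

    def __init__(self, x0, sigma0: float, popsize: int | None = None, seed: int = 0):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        n = self.mean.size
        self.n = n
        self.lam = int(popsize) if popsize else 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log((self.lam + 1) / 2.0) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.invsqrtC = np.eye(n)
        self._rng = np.random.default_rng(seed)
        self._pending: np.ndarray | None = None
        self.generation = 0

    def ask(self) -> np.ndarray:
        """Sample ``popsize`` candidate solutions, shape ``(lam, n)``."""
        z = self._rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T  # each row B @ (D * z)
        x = self.mean + self.sigma * y
        self._pending = x
        return x

    def tell(self, xs: np.ndarray, fitnesses) -> None:
        """Update the distribution from evaluated candidates (lower = better)."""
        xs = np.asarray(xs, dtype=float)
        f = np.asarray(fitnesses, dtype=float)
        if xs.shape != (self.lam, self.n) or f.size != self.lam:
            raise ValueError("tell() expects the population returned by ask()")
        order = np.argsort(f)
        sel = xs[order[: self.mu]]
        old_mean = self.mean.copy()
        self.mean = self.weights @ sel

        y_w = (self.mean - old_mean) / self.sigma
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.invsqrtC @ y_w)
        hsig = float(
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            / self.chiN
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * y_w

        artmp = (sel - old_mean) / self.sigma
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (
                np.outer(self.pc, self.pc)
                + (1 - hsig) * self.cc * (2 - self.cc) * self.C
            )
            + self.cmu * artmp.T @ np.diag(self.weights) @ artmp
        )
        self.sigma *= np.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chiN - 1)
        )
        self.generation += 1

        # refresh the eigendecomposition (cheap at n = 3)
        self.C = np.triu(self.C) + np.triu(self.C, 1).T
        d2, self.B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d2, 1e-20))
        self.invsqrtC = self.B @ np.diag(1.0 / self.D) @ self.B.T

    def optimize(self, func, max_iter: int = 100, target: float = -np.inf):
        """Run ask/tell until ``target`` is reached or ``max_iter`` passes.

        Returns ``(best_x, best_f, history)`` where history holds the
        per-iteration minimum fitness.
        """
        best_x, best_f = None, np.inf
        history = []
        for _ in range(max_iter):
            xs = self.ask()
            fs = np.array([func(x) for x in xs])
            self.tell(xs, fs)
            i = int(np.argmin(fs))
            if fs[i] < best_f:
                best_f, best_x = float(fs[i]), xs[i].copy()
            history.append(float(fs[i]))
            if best_f <= target:
                break
        return best_x, best_f, history
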