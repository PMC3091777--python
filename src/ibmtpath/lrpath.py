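"""Cutoff-free gene-set enrichment by logistic regression (LRpath), directional variant.

Instead of thresholding genes into "significant" and "not", each gene carries a
continuous significance score and set membership is modeled as

    logit P(g in S) = beta0 + beta1 * x_g,

fitted over the whole measured universe by iteratively reweighted least
squares.  A positive slope means set members concentrate among genes with
large scores; the Wald test of beta1 = 0 gives the set p-value and
Benjamini-Hochberg adjustment across all sets tested in a run gives the FDR.

In the directional variant the score is signed by the fold-change direction,

    x_g = sign(b_g) * (-ln p_g),

so up-regulated significant genes push the score positive and the sign of
beta1 reports whether a set is coordinately up- or down-regulated.  The
nondirectional variant uses the unsigned -ln p_g.

The per-gene inputs come from the moderated t-test; genes measured by several
probes are represented by the probe with the highest mean signal intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .study_model import FormatError
from .ibmt import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "DegenerateScoresError",
    "read_gmt",
    "write_gmt",
    "build_significance_scores",
    "run_lrpath",
    "enrichment_matrix",
]

P_FLOOR = 1e-300  # p-values are clamped here before taking logs


class DegenerateScoresError(ValueError):
    """All gene scores identical; the logistic slope is unidentifiable."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]
    namespace: str = "sets"

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """Ordered gene-set collection with optional restriction to a measured universe."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self.sets:
            raise FormatError(f"duplicate set id {gs.set_id!r}")
        self.sets[gs.set_id] = gs

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with the measured universe, dropping emptied sets."""
        uni = set(universe)
        out = GeneSetCollection()
        dropped = 0
        for gs in self:
            members = tuple(g for g in gs.members if g in uni)
            if members:
                out.add(GeneSet(gs.set_id, gs.name, members, gs.namespace))
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d set(s) empty after universe intersection", dropped)
        return out


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (set-id TAB description TAB member ids...)."""
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >=3")
            set_id, name, *members = fields
            if set_id in coll:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            coll.add(GeneSet(set_id, name, tuple(members)))
    if universe is not None:
        coll = coll.restricted_to(universe)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in collection:
            fh.write("\t".join((gs.set_id, gs.name) + gs.members) + "\n")


def build_significance_scores(
    moderated: pd.DataFrame,
    gene_stats: pd.DataFrame,
    gene_map: pd.Series | None = None,
    level: str = "gene",
) -> pd.DataFrame:
    """Signed log-significance scores per gene (or probe).

    ``moderated`` must carry columns ``p``; ``gene_stats`` columns ``sign``
    and ``a`` (mean intensity), both indexed by probe.  ``gene_map`` maps
    probe id -> gene id; None means probe ids are the gene ids.  At gene
    level a gene measured by several probes is represented by the probe with
    the highest mean intensity ``a``.

    Returns a frame indexed by gene (or probe) with columns ``x`` (signed
    score), ``p``, ``sign`` and ``probe`` (the representative probe).
    """
    if len(moderated) == 0:
        raise ValueError("no moderated results supplied")
    if level not in ("gene", "probe"):
        raise ValueError(f"level must be 'gene' or 'probe', got {level!r}")
    df = pd.DataFrame(
        {
            "p": moderated["p"],
            "sign": gene_stats.loc[moderated.index, "sign"],
            "a": gene_stats.loc[moderated.index, "a"],
        }
    )
    df = df[df["p"].notna()]
    if len(df) == 0:
        raise ValueError("no probes with defined p-values")
    df["probe"] = df.index
    if level == "gene":
        genes = gene_map.loc[df.index] if gene_map is not None else pd.Series(
            df.index, index=df.index
        )
        df = df.assign(gene=genes.to_numpy())
        # representative probe: highest mean signal intensity
        df = (
            df.sort_values(["gene", "a", "probe"], kind="stable")
            .groupby("gene", sort=True)
            .tail(1)
            .set_index("gene")
        )
    p = np.clip(df["p"].to_numpy(dtype=float), P_FLOOR, 1.0)
    x = df["sign"].to_numpy(dtype=float) * (-np.log(p))
    out = pd.DataFrame(
        {"x": x, "p": p, "sign": df["sign"].to_numpy(), "probe": df["probe"].to_numpy()},
        index=df.index,
    )
    out.index.name = "gene" if level == "gene" else "probe"
    return out


# ---------------------------------------------------------------------------
# Logistic fit by IRLS
# ---------------------------------------------------------------------------

MAX_ITER = 50
DEV_TOL = 1e-8
SEPARATION_BOUND = 20.0
_MU_EPS = 1e-10


def _logistic_irls(x: np.ndarray, y: np.ndarray):
    """Maximum-likelihood intercept+slope logistic fit.

    Returns (beta, se, converged): beta = (beta0, beta1), se their standard
    errors from the inverse Fisher information at the optimum.
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    ybar = y.mean()
    beta = np.array([np.log(ybar / (1.0 - ybar)), 0.0])
    dev_old = np.inf
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, np.full(2, np.nan), False
        mu_new = np.clip(expit(X @ beta), _MU_EPS, 1.0 - _MU_EPS)
        dev = -2.0 * np.sum(y * np.log(mu_new) + (1.0 - y) * np.log(1.0 - mu_new))
        if abs(dev - dev_old) < DEV_TOL:
            converged = True
            break
        dev_old = dev
    eta = X @ beta
    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
        converged = False
    return beta, se, converged


def run_lrpath(
    scores: pd.DataFrame | pd.Series,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    directional: bool = True,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Logistic-regression enrichment of every set against the score universe.

    ``scores`` is the frame from :func:`build_significance_scores` (or a bare
    Series of signed scores indexed by gene).  Sets are restricted to the
    universe and filtered to ``[min_size, max_size]`` measured members.

    Output frame (indexed by set id): ``name, n, beta1, odds_ratio,
    direction, p, fdr, enriched, status``.  ``status`` is ``"ok"`` or
    ``"unstable"`` (constant membership, separation |beta1| > 20, or
    non-convergence); unstable sets carry no p-value and are excluded from
    the FDR family.
    """
    if isinstance(scores, pd.Series):
        x_all = scores.astype(float)
    else:
        x_all = scores["x"].astype(float)
    universe = x_all.index
    if universe.has_duplicates:
        raise ValueError("score index (gene universe) contains duplicates")
    x = x_all.to_numpy()
    if not directional:
        x = np.abs(x)
    if np.ptp(x) == 0:
        raise DegenerateScoresError("all gene scores are identical")
    if len(universe) < 2 * min_size:
        raise ValueError(
            f"universe of {len(universe)} genes is too small (need >= {2 * min_size})"
        )
    restricted = sets.restricted_to(universe)
    pos = {g: i for i, g in enumerate(universe)}

    rows = []
    for gs in restricted:
        n_s = len(gs.members)
        if not (min_size <= n_s <= max_size):
            continue
        y = np.zeros(len(universe))
        y[[pos[g] for g in gs.members]] = 1.0
        if y.all() or not y.any():
            rows.append((gs.set_id, gs.name, n_s, np.nan, np.nan, "", np.nan, "unstable"))
            continue
        beta, se, converged = _logistic_irls(x, y)
        beta1, se1 = beta[1], se[1]
        if (not converged) or (not np.isfinite(beta1)) or abs(beta1) > SEPARATION_BOUND \
                or not np.isfinite(se1) or se1 <= 0:
            rows.append((gs.set_id, gs.name, n_s, beta1, np.nan, "", np.nan, "unstable"))
            continue
        wald = beta1 / se1
        p = max(2.0 * stats.norm.sf(abs(wald)), np.nextafter(0, 1))
        direction = "up" if beta1 > 0 else "down"
        rows.append((gs.set_id, gs.name, n_s, beta1, np.exp(beta1), direction, p, "ok"))

    out = pd.DataFrame(
        rows,
        columns=["set_id", "name", "n", "beta1", "odds_ratio", "direction", "p", "status"],
    ).set_index("set_id")
    out["fdr"] = np.nan
    ok = out["status"] == "ok"
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["enriched"] = ok & (out["fdr"] < fdr_threshold)
    logger.info(
        "LRpath: %d set(s) tested, %d unstable, %d enriched at FDR<%g",
        int(ok.sum()), int((~ok).sum()), int(out["enriched"].sum()), fdr_threshold,
    )
    return out


def enrichment_matrix(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Signed -log10(p) matrix (terms x comparisons) for cross-condition clustering.

    Entry (term, comparison) = direction sign * -log10(p); term-comparison
    pairs that were not tested (or were unstable) are 0.  Columns follow the
    mapping's order; rows are the sorted union of tested set ids.
    """
    if not results:
        raise ValueError("need at least one comparison")
    terms = sorted({t for df in results.values() for t in df.index[df["status"] == "ok"]})
    mat = pd.DataFrame(0.0, index=pd.Index(terms, name="set_id"), columns=list(results))
    for comp, df in results.items():
        ok = df[df["status"] == "ok"]
        signs = np.where(ok["direction"].to_numpy() == "up", 1.0, -1.0)
        mat.loc[ok.index, comp] = signs * (-np.log10(ok["p"].to_numpy(dtype=float)))
    return mat
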