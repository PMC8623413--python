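"""Parsimony mapping of Y-gene gains/losses on a species tree and rate-ratio
estimation.

Each gene is assumed to be gained on exactly one branch (a single
duplication-to-Y event, Dollo-style); per-lineage losses of either the
original autosomal/X source copy or of the Y copy then explain the observed
leaf states {Y, XA, absent, unknown}.  The most-parsimonious scenario (fewest
total events) is chosen, with ties broken toward the most recent acquisition
branch and reported.

Rates are modeled as independent Poissons: gains at rate g per My of branch
time, losses at rate l per gene-My of Y-residency.  The gain:loss ratio
g-hat / l-hat is tested against H0: g = l with a likelihood-ratio test, and a
95% confidence interval is obtained by profiling the likelihood over the
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.optimize import brentq
from scipy.stats import chi2

STATE_Y = "Y"
STATE_XA = "XA"
STATE_ABSENT = "absent"
STATE_UNKNOWN = "unknown"
_STATES = {STATE_Y, STATE_XA, STATE_ABSENT, STATE_UNKNOWN}

ROOT_LABEL = "root"


# ---------------------------------------------------------------------------
# tree bookkeeping


def edge_labels(tree) -> dict[int, str]:
    """Stable human-readable labels for every edge (keyed by id(edge)).

    Leaf edges are labeled by their taxon; internal edges by the sorted,
    '+'-joined labels of their descendant leaves; the stem above the root is
    labeled ``root``.
    """
    labels: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        edge = node.edge
        if edge.tail_node is None:
            labels[id(edge)] = ROOT_LABEL
        elif node.is_leaf():
            labels[id(edge)] = node.taxon.label
        else:
            leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
            labels[id(edge)] = "+".join(leaves)
    return labels


def _edge_index(tree):
    """Per-edge records: label, node, clade leaf set, depth (root distance)."""
    labels = edge_labels(tree)
    records = {}
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depths[id(parent)] + (node.edge.length or 1.0)
        depths[id(node)] = d
        lab = labels[id(node.edge)]
        records[lab] = {
            "node": node,
            "clade": frozenset(lf.taxon.label for lf in node.leaf_iter()),
            "depth": d,
        }
    return records


# ---------------------------------------------------------------------------
# event map


@dataclass
class EventMap:
    """Gains/losses per branch, with the exposures the rate model needs."""

    tree: object
    gains: dict[str, list[str]]
    losses: dict[str, list[str]]
    gain_exposure: dict[str, float]  # branch -> My of branch time
    loss_exposure: dict[str, float]  # branch -> gene-My of Y-residency

    def totals(self) -> tuple[int, int, float, float]:
        G = sum(len(v) for v in self.gains.values())
        L = sum(len(v) for v in self.losses.values())
        Tg = float(sum(self.gain_exposure.values()))
        Tl = float(sum(self.loss_exposure.values()))
        return G, L, Tg, Tl

    def to_frame(self):
        import pandas as pd

        rows = []
        for lab in self.gain_exposure:
            rows.append(
                {
                    "branch": lab,
                    "n_gains": len(self.gains.get(lab, [])),
                    "n_losses": len(self.losses.get(lab, [])),
                    "gains": ",".join(self.gains.get(lab, [])),
                    "losses": ",".join(self.losses.get(lab, [])),
                    "gain_exposure_my": self.gain_exposure[lab],
                    "loss_exposure_gene_my": self.loss_exposure.get(lab, 0.0),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class Scenario:
    """One most-parsimonious explanation of a gene's leaf states."""

    gene_id: str
    gain_edge: str
    y_loss_edges: tuple[str, ...]
    source_loss_edges: tuple[str, ...]
    cost: int
    tied_gain_edges: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# parsimony


def _min_cover(top_node, allowed, must, labels) -> list[str] | None:
    """Fewest edges whose removal deletes the copy from exactly `must` leaves.

    `allowed` are leaves that may lose the copy (must plus unknowns); leaves
    outside `allowed` must keep it.  Returns the chosen edge labels, or None
    if impossible (never happens when must is a subset of allowed).  If the
    whole subtree may be deleted, the edge above `top_node` is used.
    """

    chosen: list[str] = []

    def rec(node) -> tuple[bool, bool]:
        # returns (entire subtree allowed to lose, subtree contains a must-leaf)
        if node.is_leaf():
            lf = node.taxon.label
            return lf in allowed, lf in must
        results = [(child, *rec(child)) for child in node.child_nodes()]
        if all(ok for _, ok, _ in results):
            return True, any(m for _, _, m in results)
        for child, ok, has_must in results:
            if ok and has_must:
                chosen.append(labels[id(child.edge)])
        return False, any(m for _, _, m in results)

    ok, has_must = rec(top_node)
    if ok and has_must:
        return [labels[id(top_node.edge)]]
    return chosen


def infer_acquisition_branch(states: Mapping[str, str], tree) -> Scenario:
    """Most-parsimonious acquisition branch for one gene.

    ``states`` maps leaf name -> {Y, XA, absent, unknown} (missing leaves are
    treated as unknown).  The scenario comprises one duplication-to-Y on the
    returned branch, plus the minimal per-lineage losses of the source copy
    (where leaves show Y or absent) and of the Y copy (where in-clade leaves
    show XA or absent).  Ties are broken toward the most recent branch and
    reported in ``tied_gain_edges``.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for leaf, st in states.items():
        if st not in _STATES:
            raise ValueError(f"invalid state {st!r} for leaf {leaf!r}")
    get = lambda lf: states.get(lf, STATE_UNKNOWN)
    y_leaves = {lf for lf in leaves if get(lf) == STATE_Y}
    xa_leaves = {lf for lf in leaves if get(lf) == STATE_XA}
    abs_leaves = {lf for lf in leaves if get(lf) == STATE_ABSENT}
    unk_leaves = {lf for lf in leaves if get(lf) == STATE_UNKNOWN}
    if not y_leaves:
        if xa_leaves or abs_leaves:
            raise ValueError("gene has no Y-state leaf; no acquisition to infer")
        raise ValueError("all states unknown")

    index = _edge_index(tree)
    labels = edge_labels(tree)

    # Source-copy losses do not depend on the gain branch: the source must be
    # gone wherever the leaf shows Y or absent, kept wherever it shows XA.
    src_losses = _min_cover(
        tree.seed_node,
        allowed=y_leaves | abs_leaves | unk_leaves,
        must=y_leaves | abs_leaves,
        labels=labels,
    )

    best: list[tuple[int, float, str, tuple]] = []
    for lab, rec in index.items():
        clade = rec["clade"]
        if not y_leaves <= clade:
            continue
        must_y = (xa_leaves | abs_leaves) & clade
        y_losses = _min_cover(
            rec["node"],
            allowed=must_y | (unk_leaves & clade),
            must=must_y,
            labels=labels,
        )
        cost = 1 + len(y_losses) + len(src_losses)
        best.append((cost, rec["depth"], lab, (tuple(y_losses), tuple(src_losses))))

    min_cost = min(b[0] for b in best)
    optimal = [b for b in best if b[0] == min_cost]
    # most recent acquisition = greatest depth from root; deterministic final
    # tie-break on the label
    optimal.sort(key=lambda b: (-b[1], b[2]))
    cost, _, gain_edge, (y_losses, src_losses_t) = optimal[0]
    return Scenario(
        gene_id="",
        gain_edge=gain_edge,
        y_loss_edges=y_losses,
        source_loss_edges=src_losses_t,
        cost=cost,
        tied_gain_edges=tuple(b[2] for b in optimal[1:]),
    )


def infer_all(presence, tree, exclude_genes: Iterable[str] = ()) -> dict[str, Scenario]:
    """Scenarios for every gene of a presence matrix (genes x species).

    ``presence`` is a DataFrame (index gene ids, columns species) or a nested
    mapping gene -> {species: state}.  ``exclude_genes`` drops genes (e.g.
    recent duplications whose source copy is still functional) before mapping.
    """
    import pandas as pd

    if isinstance(presence, pd.DataFrame):
        items = ((g, presence.loc[g].to_dict()) for g in presence.index)
    else:
        items = presence.items()
    excluded = set(exclude_genes)
    out = {}
    for gene, states in items:
        if gene in excluded:
            continue
        sc = infer_acquisition_branch(states, tree)
        sc.gene_id = gene
        out[gene] = sc
    return out


# ---------------------------------------------------------------------------
# scenario aggregation


def build_event_map(scenarios: Mapping[str, Scenario], tree) -> EventMap:
    """Aggregate per-gene scenarios into per-branch events and exposures.

    Event times within a branch are unknown, so gains and losses are placed
    at branch midpoints for exposure bookkeeping: a gene contributes half the
    gain branch, the full length of every Y-resident branch below it, and
    half of each loss branch.
    """
    index = _edge_index(tree)
    labels = {lab: rec for lab, rec in index.items()}
    gains: dict[str, list[str]] = {lab: [] for lab in index}
    losses: dict[str, list[str]] = {lab: [] for lab in index}
    gain_exposure = {
        lab: (rec["node"].edge.length or 0.0) for lab, rec in index.items()
    }
    loss_exposure = {lab: 0.0 for lab in index}

    for gene, sc in scenarios.items():
        if sc.gain_edge not in labels:
            raise ValueError(f"unknown gain edge {sc.gain_edge!r}")
        gain_rec = labels[sc.gain_edge]
        clade = gain_rec["clade"]
        loss_set = set(sc.y_loss_edges)
        for e in loss_set:
            if e not in labels or not labels[e]["clade"] <= clade:
                raise ValueError(
                    f"gene {gene}: loss on {e!r} precedes its gain on {sc.gain_edge!r}"
                )
        gains[sc.gain_edge].append(gene)

        def resident(lab) -> bool:
            # resident on a branch iff it is in the gain clade and no loss
            # branch lies on the path between the gain branch and it
            rec = labels[lab]
            if not rec["clade"] <= clade:
                return False
            node = rec["node"]
            while node is not None:
                nlab = None
                for cand, crec in labels.items():
                    if crec["node"] is node:
                        nlab = cand
                        break
                if nlab in loss_set and nlab != lab:
                    return False
                if nlab == sc.gain_edge:
                    return True
                node = node.parent_node
            return False

        for lab, rec in labels.items():
            elen = rec["node"].edge.length or 0.0
            if lab == sc.gain_edge:
                loss_exposure[lab] += (
                    elen / 4.0 if lab in loss_set else elen / 2.0
                )
                if lab in loss_set:
                    losses[lab].append(gene)
                continue
            if not resident(lab):
                continue
            if lab in loss_set:
                loss_exposure[lab] += elen / 2.0
                losses[lab].append(gene)
            else:
                loss_exposure[lab] += elen

    return EventMap(
        tree=tree,
        gains=gains,
        losses=losses,
        gain_exposure=gain_exposure,
        loss_exposure=loss_exposure,
    )


# ---------------------------------------------------------------------------
# rate-ratio estimation


@dataclass
class GainLossEstimate:
    """ML gain:loss rate ratio with LRT p-value and profile CI."""

    ratio_hat: float
    p_value: float
    ci_low: float
    ci_high: float
    n_gains: int
    n_losses: int
    gain_exposure: float
    loss_exposure: float
    flagged: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "ratio_hat": self.ratio_hat,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_gains": self.n_gains,
            "n_losses": self.n_losses,
            "gain_exposure_my": self.gain_exposure,
            "loss_exposure_gene_my": self.loss_exposure,
            "flagged": self.flagged,
            "note": self.note,
        }


def _xlogy(x: float, y: float) -> float:
    return 0.0 if x == 0 else x * math.log(y)


def estimate_ratio(event_map: EventMap, alpha: float = 0.05) -> GainLossEstimate:
    """ML estimate of the gain:loss rate ratio from an event map.

    Gains ~ Poisson(g * T_gain) with T_gain the summed branch time; losses ~
    Poisson(l * T_loss) with T_loss the summed gene-My of Y-residency.  The
    p-value is a 1-df likelihood-ratio test of H0: g = l; the CI profiles the
    likelihood over rho = g/l.  With zero observed losses the ratio is a
    lower bound (ci_high = +inf) and the estimate is flagged.
    """
    G, L, Tg, Tl = event_map.totals()
    if Tg <= 0:
        raise ValueError("total gain exposure must be positive")
    if Tl <= 0:
        if L > 0:
            raise ValueError("losses observed with zero loss exposure")
        return GainLossEstimate(
            ratio_hat=math.nan, p_value=math.nan, ci_low=math.nan, ci_high=math.nan,
            n_gains=G, n_losses=L, gain_exposure=Tg, loss_exposure=Tl,
            flagged=True, note="no Y-residency accumulated; loss rate undefined",
        )

    ghat, lhat = G / Tg, L / Tl
    loglik_full = _xlogy(G, ghat * Tg) - ghat * Tg + _xlogy(L, lhat * Tl) - lhat * Tl
    r0 = (G + L) / (Tg + Tl)
    loglik_null = _xlogy(G, r0 * Tg) + _xlogy(L, r0 * Tl) - r0 * (Tg + Tl)
    lrt = max(0.0, 2.0 * (loglik_full - loglik_null))
    p_value = float(chi2.sf(lrt, df=1))
    q = float(chi2.ppf(1.0 - alpha, df=1))

    def profile(theta: float) -> float:
        # profile log-likelihood at rho = exp(theta); nuisance l maximized
        # in closed form: l(rho) = (G + L) / (rho*Tg + Tl)
        rho = math.exp(theta)
        lam = (G + L) / (rho * Tg + Tl)
        return _xlogy(G, rho * lam * Tg) + _xlogy(L, lam * Tl) - (G + L)

    if G > 0 and L > 0:
        ratio = ghat / lhat
        theta_hat = math.log(ratio)
        sup = profile(theta_hat)
        f = lambda th: 2.0 * (sup - profile(th)) - q
        lo = theta_hat
        while f(lo) < 0:
            lo -= 1.0
        ci_low = math.exp(brentq(f, lo, theta_hat, xtol=1e-9))
        hi = theta_hat
        while f(hi) < 0:
            hi += 1.0
        ci_high = math.exp(brentq(f, theta_hat, hi, xtol=1e-9))
        return GainLossEstimate(
            ratio_hat=ratio, p_value=p_value, ci_low=ci_low, ci_high=ci_high,
            n_gains=G, n_losses=L, gain_exposure=Tg, loss_exposure=Tl,
        )

    if G > 0 and L == 0:
        sup = _xlogy(G, G) - G  # limit of the profile as rho -> inf
        f = lambda th: 2.0 * (sup - profile(th)) - q
        lo = math.log(ghat * Tl / max(G, 1))  # generous start
        while f(lo) < 0:
            lo -= 1.0
        hi = lo + 1.0
        while f(hi) >= 0:
            hi += 1.0
        ci_low = math.exp(brentq(f, lo, hi, xtol=1e-9))
        return GainLossEstimate(
            ratio_hat=math.inf, p_value=p_value, ci_low=ci_low, ci_high=math.inf,
            n_gains=G, n_losses=L, gain_exposure=Tg, loss_exposure=Tl,
            flagged=True, note="no losses observed; ratio is a lower bound",
        )

    if G == 0 and L > 0:
        sup = _xlogy(L, L) - L
        f = lambda th: 2.0 * (sup - profile(th)) - q
        hi = 0.0
        while f(hi) < 0:
            hi += 1.0
        lo = hi - 1.0
        while f(lo) >= 0:
            lo -= 1.0
        ci_high = math.exp(brentq(f, lo, hi, xtol=1e-9))
        return GainLossEstimate(
            ratio_hat=0.0, p_value=p_value, ci_low=0.0, ci_high=ci_high,
            n_gains=G, n_losses=L, gain_exposure=Tg, loss_exposure=Tl,
            flagged=True, note="no gains observed; ratio is an upper bound",
        )

    return GainLossEstimate(
        ratio_hat=math.nan, p_value=math.nan, ci_low=math.nan, ci_high=math.nan,
        n_gains=0, n_losses=0, gain_exposure=Tg, loss_exposure=Tl,
        flagged=True, note="no events observed",
    )
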