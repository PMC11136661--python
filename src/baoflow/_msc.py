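"""Per-site multispecies-coalescent simulation kernel.

Each site is an independent gene tree drawn under the multispecies
coalescent on a fixed, ultrametric species tree (times in coalescent
units), with one haploid lineage per species.  Optionally a single
introgression pulse acts at time ``t_m``, per site with probability
``gamma``, in one of two modes: ``join`` (the recipient species'
lineage coalesces onto the donor's lineage at ``t_m`` — complete
haplotype replacement by the donor, the model under which the f4-ratio
estimates ``gamma`` without attenuation) or ``migrate`` (the recipient
lineage is moved, backwards in time, into the donor's population and
coalesces there at the ordinary rate).  Exactly one mutation is then placed
uniformly at random on the gene tree and the subtending leaves carry
the derived allele (emitted as homozygous-diploid genotype 2).

The species tree is encoded as flat arrays: nodes ``0..n_taxa-1`` are
leaves at height 0; internal nodes follow in increasing height order
with the root last; ``parent``/``child1``/``child2``/``height`` describe
the topology.  A "population" is the branch above a node and is
identified by that node's id.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_sites(
    n_sites,
    n_taxa,
    child1,
    child2,
    ev_times,
    ev_nodes,
    pulse_time,
    pulse_join,
    gamma,
    recipient_leaf,
    donor_pop,
    want_topo,
    trio,
    seed,
):  # pragma: no cover - exercised through python wrappers
    np.random.seed(seed)
    n_gnodes = 2 * n_taxa - 1
    geno = np.zeros((n_sites, n_taxa), dtype=np.int8)
    topo = np.full(n_sites, -1, dtype=np.int8)

    g_par = np.empty(n_gnodes, dtype=np.int64)
    g_time = np.empty(n_gnodes, dtype=np.float64)
    g_c1 = np.empty(n_gnodes, dtype=np.int64)
    g_c2 = np.empty(n_gnodes, dtype=np.int64)
    lin_node = np.empty(n_taxa, dtype=np.int64)
    lin_pop = np.empty(n_taxa, dtype=np.int64)
    pops = np.empty(n_taxa, dtype=np.int64)
    idx = np.empty(n_taxa, dtype=np.int64)
    stack = np.empty(n_gnodes, dtype=np.int64)
    anc_time = np.empty(n_gnodes, dtype=np.float64)
    n_ev = len(ev_times)

    for s in range(n_sites):
        for i in range(n_taxa):
            lin_node[i] = i
            lin_pop[i] = i
        for g in range(n_gnodes):
            g_par[g] = -1
        for i in range(n_taxa):
            g_time[i] = 0.0
        nlin = n_taxa
        nxt = n_taxa
        t_cur = 0.0
        pulse_done = not (pulse_time >= 0.0 and np.random.random() < gamma[s])
        e = 0
        while nlin > 1:
            if not pulse_done and (e >= n_ev or pulse_time <= ev_times[e]):
                t_next = pulse_time
                kind = 0
            elif e < n_ev:
                t_next = ev_times[e]
                kind = 1
            else:
                t_next = 1.0e300
                kind = 2
            # coalesce within each population over [t_cur, t_next)
            npop = 0
            for i in range(nlin):
                found = False
                for j in range(npop):
                    if pops[j] == lin_pop[i]:
                        found = True
                        break
                if not found:
                    pops[npop] = lin_pop[i]
                    npop += 1
            for pi in range(npop):
                p = pops[pi]
                t = t_cur
                while True:
                    k = 0
                    for i in range(nlin):
                        if lin_pop[i] == p:
                            idx[k] = i
                            k += 1
                    if k < 2:
                        break
                    rate = k * (k - 1) / 2.0
                    t += np.random.exponential(1.0 / rate)
                    if t >= t_next:
                        break
                    a = np.random.randint(0, k)
                    b = np.random.randint(0, k - 1)
                    if b >= a:
                        b += 1
                    ia = idx[a]
                    ib = idx[b]
                    g_c1[nxt] = lin_node[ia]
                    g_c2[nxt] = lin_node[ib]
                    g_time[nxt] = t
                    g_par[lin_node[ia]] = nxt
                    g_par[lin_node[ib]] = nxt
                    lin_node[ia] = nxt
                    lin_node[ib] = lin_node[nlin - 1]
                    lin_pop[ib] = lin_pop[nlin - 1]
                    nlin -= 1
                    nxt += 1
            if nlin <= 1:
                break
            t_cur = t_next
            if kind == 0:
                if pulse_join:
                    # recipient lineage coalesces onto the donor lineage
                    ir = -1
                    idn = -1
                    for i in range(nlin):
                        if lin_pop[i] == recipient_leaf:
                            ir = i
                        elif lin_pop[i] == donor_pop:
                            idn = i
                    if ir >= 0 and idn >= 0:
                        g_c1[nxt] = lin_node[ir]
                        g_c2[nxt] = lin_node[idn]
                        g_time[nxt] = t_cur
                        g_par[lin_node[ir]] = nxt
                        g_par[lin_node[idn]] = nxt
                        lin_node[idn] = nxt
                        lin_node[ir] = lin_node[nlin - 1]
                        lin_pop[ir] = lin_pop[nlin - 1]
                        nlin -= 1
                        nxt += 1
                else:
                    for i in range(nlin):
                        if lin_pop[i] == recipient_leaf:
                            lin_pop[i] = donor_pop
                            break
                pulse_done = True
            elif kind == 1:
                node = ev_nodes[e]
                c1 = child1[node]
                c2 = child2[node]
                for i in range(nlin):
                    if lin_pop[i] == c1 or lin_pop[i] == c2:
                        lin_pop[i] = node
                e += 1

        # one mutation uniform on total branch length
        total = 0.0
        for g in range(nxt):
            if g_par[g] >= 0:
                total += g_time[g_par[g]] - g_time[g]
        u = np.random.random() * total
        mut = -1
        acc = 0.0
        for g in range(nxt):
            if g_par[g] >= 0:
                acc += g_time[g_par[g]] - g_time[g]
                if u < acc:
                    mut = g
                    break
        if mut < 0:
            for g in range(nxt - 1, -1, -1):
                if g_par[g] >= 0:
                    mut = g
                    break
        sp = 0
        stack[sp] = mut
        sp += 1
        while sp > 0:
            sp -= 1
            g = stack[sp]
            if g < n_taxa:
                geno[s, g] = 2
            else:
                stack[sp] = g_c1[g]
                stack[sp + 1] = g_c2[g]
                sp += 2

        if want_topo:
            # restricted topology of the trio: the pair with the smallest
            # pairwise coalescence time is sister
            t01 = _mrca_time(trio[0], trio[1], g_par, g_time, anc_time, n_taxa)
            t12 = _mrca_time(trio[1], trio[2], g_par, g_time, anc_time, n_taxa)
            t02 = _mrca_time(trio[0], trio[2], g_par, g_time, anc_time, n_taxa)
            if t01 <= t12 and t01 <= t02:
                topo[s] = 0
            elif t12 <= t02:
                topo[s] = 1
            else:
                topo[s] = 2
    return geno, topo


@njit(cache=True)
def _mrca_time(x, y, g_par, g_time, anc_time, n_taxa):  # pragma: no cover
    for g in range(len(anc_time)):
        anc_time[g] = -1.0
    g = x
    while g >= 0:
        anc_time[g] = g_time[g]
        g = g_par[g]
    g = y
    while g >= 0:
        if anc_time[g] >= 0.0:
            return g_time[g]
        g = g_par[g]
    return np.inf


class SpeciesTreeEncoding:
    """Flat-array encoding of an ultrametric species tree for the kernel."""

    def __init__(self, labels, child1, child2, height):
        self.labels = list(labels)
        self.child1 = np.asarray(child1, dtype=np.int64)
        self.child2 = np.asarray(child2, dtype=np.int64)
        self.height = np.asarray(height, dtype=np.float64)
        n = len(self.labels)
        self.n_taxa = n
        internal = np.arange(n, 2 * n - 1)
        order = internal[np.argsort(self.height[internal], kind="stable")]
        self.ev_times = self.height[order]
        self.ev_nodes = order.astype(np.int64)
        self._parent = np.full(2 * n - 1, -1, dtype=np.int64)
        for node in internal:
            self._parent[self.child1[node]] = node
            self._parent[self.child2[node]] = node

    def leaf_index(self, label) -> int:
        return self.labels.index(label)

    def pop_at(self, leaf: int, t: float) -> int:
        """The species-tree branch containing ``leaf``'s ancestry at time t."""
        node = leaf
        while self._parent[node] >= 0 and self.height[self._parent[node]] <= t:
            node = self._parent[node]
        return node

    @classmethod
    def from_newick(cls, newick: str, tol: float = 1e-9) -> "SpeciesTreeEncoding":
        """Encode a rooted, ultrametric newick with coalescent-unit lengths."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        n = len(labels)
        ids: dict = {}
        for i, lf in enumerate(leaves):
            ids[lf] = i
        depth = {}
        for node in tree.preorder_node_iter():
            d = 0.0 if node.parent_node is None else depth[node.parent_node] + (
                node.edge.length or 0.0
            )
            depth[node] = d
        max_depth = max(depth[lf] for lf in leaves)
        for lf in leaves:
            if abs(depth[lf] - max_depth) > tol:
                raise ValueError("species tree must be ultrametric in coalescent units")
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        internals.sort(key=lambda nd: max_depth - depth[nd])
        child1 = np.full(2 * n - 1, -1, dtype=np.int64)
        child2 = np.full(2 * n - 1, -1, dtype=np.int64)
        height = np.zeros(2 * n - 1, dtype=np.float64)
        nxt = n
        for nd in internals:
            ch = nd.child_nodes()
            if len(ch) != 2:
                raise ValueError("species tree must be binary")
            ids[nd] = nxt
            child1[nxt] = ids[ch[0]]
            child2[nxt] = ids[ch[1]]
            height[nxt] = max_depth - depth[nd]
            nxt += 1
        return cls(labels, child1, child2, height)


def run_msc(
    enc: SpeciesTreeEncoding,
    n_sites: int,
    gamma,
    seed: int,
    t_m: float = -1.0,
    donor: str | None = None,
    recipient: str | None = None,
    trio: tuple[int, int, int] | None = None,
    mode: str = "join",
):
    """Run the kernel; ``gamma`` may be a scalar or per-site array.

    Returns ``(geno, topo)`` where geno is (n_sites, n_taxa) int8 in
    {0, 2} and topo the restricted trio topology codes (or -1 when no
    trio is requested).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if mode not in ("join", "migrate"):
        raise ValueError("pulse mode must be 'join' or 'migrate'")
    gamma_arr = np.broadcast_to(np.asarray(gamma, dtype=np.float64), (n_sites,)).copy()
    if t_m >= 0.0 and (gamma_arr > 0).any():
        if donor is None or recipient is None:
            raise ValueError("donor and recipient required when gamma > 0")
        rec = enc.leaf_index(recipient)
        if enc.height[enc._parent[rec]] <= t_m:
            raise ValueError("pulse time must predate the recipient's first split")
        don = enc.leaf_index(donor)
        if mode == "join":
            if enc.height[enc._parent[don]] <= t_m:
                raise ValueError("join pulse needs t_m below the donor's first split")
            don_pop = don
        else:
            don_pop = enc.pop_at(don, t_m)
        pulse_time = t_m
    else:
        rec, don_pop, pulse_time = 0, 0, -1.0
    want_topo = trio is not None
    trio_arr = np.asarray(trio if trio is not None else (0, 1, 2), dtype=np.int64)
    return simulate_sites(
        n_sites,
        enc.n_taxa,
        enc.child1,
        enc.child2,
        enc.ev_times,
        enc.ev_nodes,
        pulse_time,
        mode == "join",
        gamma_arr,
        rec,
        don_pop,
        want_topo,
        trio_arr,
        int(seed),
    )
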