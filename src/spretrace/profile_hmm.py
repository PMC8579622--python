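"""Nucleotide profile hidden Markov model: build, local search, calibration.

The model is a Plan-7-style local architecture: match states M_1..M_M with
position-specific emissions, insert states I_1..I_{M-1}, silent delete states
D_2..D_M, uniform local entry B->M_j (probability 1/M each) and local exit
M_j->E. There is no flanking self-loop segment; multiple hits per target are
obtained by masking accepted spans and rescanning. Bit scores are
log2(path probability / background probability of the aligned span), so a
single-match model emitting its residue with probability 1 scores exactly
2 bits against a uniform background.

E-values follow the classical extreme-value treatment: best-per-sequence
local Viterbi scores on i.i.d. background sequences are fitted to a Gumbel
distribution (location mu, scale 1/lambda) by maximum likelihood, and
E(s) = N_eff * (1 - exp(-exp(-lambda*(s - mu)))) where N_eff counts the
effective number of independent search targets. These statistics honor the
standard E < 1e-5 reporting threshold; they are not meant to be numerically
interchangeable with any external search tool's internal calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from ._dna import BASES, encode, random_seq, revcomp
from .seed_search import Alignment, GAP

NEG = -1.0e30  # effectively -inf, safe under addition in the kernels
_MASK_CODE = 5

DEFAULT_SEED = 42


class ModelError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class HmmHit:
    """A scored, stranded local match on one target.

    S and E are 1-based inclusive coordinates on the target plus strand with
    S <= E always; ``strand`` carries orientation. ``aligned_row`` places the
    hit residues in model-column coordinates (deletions as "-", insertions
    dropped), ready for realignment into the next search cycle.
    """

    target_id: str
    S: int
    E: int
    strand: str
    bit_score: float
    e_value: float
    path: list[str] = field(default_factory=list)
    aligned_row: str = ""

    @property
    def interval(self):
        from .io_formats import GenomicInterval

        return GenomicInterval(self.target_id, self.S - 1, self.E, self.strand)


@dataclass
class ProfileHMM:
    """Profile HMM parameters plus Gumbel calibration.

    Probability (not log) parameters are stored; the scoring kernels use
    precomputed log2-odds tables. Transition slots that do not exist at the
    model edges (e.g. M_M -> M) hold 0 with the exit taking all mass.
    """

    match_emissions: np.ndarray  # (M, 4)
    insert_emissions: np.ndarray  # (M + 1, 4); rows 1..M-1 used
    t_mm: np.ndarray  # (M,) M_j -> M_{j+1}
    t_mi: np.ndarray  # (M,) M_j -> I_j
    t_md: np.ndarray  # (M,) M_j -> D_{j+1}
    t_me: np.ndarray  # (M,) M_j -> E (local exit)
    t_im: np.ndarray  # (M,) I_j -> M_{j+1}
    t_ii: np.ndarray  # (M,) I_j -> I_j
    t_dm: np.ndarray  # (M,) D_j -> M_{j+1}
    t_dd: np.ndarray  # (M,) D_j -> D_{j+1}
    entry: np.ndarray  # (M,) B -> M_j
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    mu: float | None = None
    lam: float | None = None
    n_eff: float | None = None

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.match_emissions.argmax(axis=1))

    def validate(self) -> None:
        M = self.M
        if M < 1:
            raise ModelError("model needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("match emission rows must sum to 1")
        used = self.insert_emissions[1:M]
        if used.size and not np.allclose(used.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("insert emission rows must sum to 1")
        out_m = self.t_mm + self.t_mi + self.t_md + self.t_me
        if not np.allclose(out_m, 1.0, atol=1e-9):
            raise ModelError("match outgoing transitions must sum to 1")
        if M > 1:
            if not np.allclose((self.t_im + self.t_ii)[: M - 1], 1.0, atol=1e-9):
                raise ModelError("insert outgoing transitions must sum to 1")
            if not np.allclose((self.t_dm + self.t_dd)[1 : M - 1], 1.0, atol=1e-9):
                raise ModelError("delete outgoing transitions must sum to 1")
        if not math.isclose(self.entry.sum(), 1.0, abs_tol=1e-9):
            raise ModelError("entry distribution must sum to 1")
        if self.lam is not None and self.lam <= 0:
            raise ModelError("lambda must be positive")

    # ---- log-odds tables for the kernels -------------------------------

    def _tables(self):
        q = self.background
        M = self.M

        def lo(p):  # emission log2-odds with N neutral, mask -inf
            t = np.full((M + 1, 6), NEG)
            t[1:, :4] = np.log2(np.maximum(p, 1e-300) / q)
            t[:, 4] = 0.0  # N: missing data, scored at background
            return t

        mlo = lo(self.match_emissions)
        ilo = lo(self.insert_emissions[1:])
        with np.errstate(divide="ignore"):
            def l2(x):
                out = np.full(M + 1, NEG)
                out[1:] = np.where(x > 0, np.log2(np.maximum(x, 1e-300)), NEG)
                return out

            return (
                mlo,
                ilo,
                l2(self.entry),
                l2(self.t_mm),
                l2(self.t_mi),
                l2(self.t_md),
                l2(self.t_im),
                l2(self.t_ii),
                l2(self.t_dm),
                l2(self.t_dd),
                l2(self.t_me),
            )

    # ---- serialization --------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("SPRETRACE-HMM 1\n")
            fh.write(f"M {self.M}\n")
            fh.write("BG " + " ".join(f"{x:.17g}" for x in self.background) + "\n")
            if self.calibrated:
                fh.write(f"STATS {self.mu:.17g} {self.lam:.17g}\n")
            if self.n_eff is not None:
                fh.write(f"NEFF {self.n_eff:.17g}\n")
            names = [
                "MATCH", "INSERT", "TMM", "TMI", "TMD", "TME",
                "TIM", "TII", "TDM", "TDD", "ENTRY",
            ]
            arrays = [
                self.match_emissions, self.insert_emissions, self.t_mm,
                self.t_mi, self.t_md, self.t_me, self.t_im, self.t_ii,
                self.t_dm, self.t_dd, self.entry,
            ]
            for name, arr in zip(names, arrays):
                arr = np.atleast_2d(arr)
                fh.write(f"{name} {arr.shape[0]} {arr.shape[1]}\n")
                for row in arr:
                    fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or not lines[0].startswith("SPRETRACE-HMM"):
            raise ModelError(f"{path}: not a spretrace model file")
        i = 1
        fields: dict[str, np.ndarray] = {}
        mu = lam = n_eff = None
        background = np.full(4, 0.25)
        while i < len(lines):
            parts = lines[i].split()
            key = parts[0]
            if key == "M":
                i += 1
            elif key == "BG":
                background = np.array([float(x) for x in parts[1:]])
                i += 1
            elif key == "STATS":
                mu, lam = float(parts[1]), float(parts[2])
                i += 1
            elif key == "NEFF":
                n_eff = float(parts[1])
                i += 1
            else:
                nr, nc = int(parts[1]), int(parts[2])
                block = [
                    [float(x) for x in lines[i + 1 + r].split()] for r in range(nr)
                ]
                fields[key] = np.array(block)
                i += 1 + nr
        flat = lambda k: fields[k].ravel()
        hmm = cls(
            match_emissions=fields["MATCH"],
            insert_emissions=fields["INSERT"],
            t_mm=flat("TMM"), t_mi=flat("TMI"), t_md=flat("TMD"),
            t_me=flat("TME"), t_im=flat("TIM"), t_ii=flat("TII"),
            t_dm=flat("TDM"), t_dd=flat("TDD"), entry=flat("ENTRY"),
            background=background, mu=mu, lam=lam, n_eff=n_eff,
        )
        hmm.validate()
        return hmm


# ---------------------------------------------------------------------------
# Model construction from an alignment


def build_hmm(
    alignment: Alignment,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    exit_prob: float = 0.01,
) -> ProfileHMM:
    """Estimate a profile HMM from a gapped alignment.

    Columns with gap fraction < ``gap_threshold`` become match states.
    Emissions use background-proportional additive pseudocounts:
    p = (counts + pseudocount * q) / (total + pseudocount). Transition
    distributions are estimated from per-row state paths with the same
    scheme; ``exit_prob`` mass is reserved for the local exit at every
    internal match state (the last match state exits with probability 1).
    N characters are treated as missing data and contribute to no counts.
    """
    if alignment.n_rows == 0:
        raise ModelError("empty alignment")
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    q = q / q.sum()
    rows = alignment.rows
    width = alignment.width
    ncols = width
    base_idx = {b: i for i, b in enumerate(BASES)}

    gap_frac = np.array(
        [sum(r[c] == GAP for r in rows) / len(rows) for c in range(ncols)]
    )
    match_cols = [c for c in range(ncols) if gap_frac[c] < gap_threshold]
    if not match_cols:
        raise ModelError("no columns below the gap threshold; cannot build model")
    M = len(match_cols)

    mcounts = np.zeros((M, 4))
    icounts = np.zeros((M + 1, 4))
    # transition counts per node: mm mi md / im ii / dm dd
    tc = {k: np.zeros(M) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    col_to_node = {c: j for j, c in enumerate(match_cols)}
    for r in rows:
        # emissions
        for j, c in enumerate(match_cols):
            ch = r[c]
            if ch in base_idx:
                mcounts[j, base_idx[ch]] += 1
        # walk: node states (M or D) and insert runs between nodes
        states = []  # (kind, node_index_1based)
        for j, c in enumerate(match_cols):
            states.append(("M" if r[c] != GAP else "D", j + 1))
        inserts = np.zeros(M + 1, dtype=int)  # residues between node j and j+1
        node = 0
        for c in range(ncols):
            if c in col_to_node:
                node = col_to_node[c] + 1
            elif r[c] != GAP:
                if 1 <= node < M:  # local model: no I_0 / I_M
                    inserts[node] += 1
                    if r[c] in base_idx:
                        icounts[node, base_idx[r[c]]] += 1
        for j in range(1, M):
            src = states[j - 1][0]
            dst = states[j][0]
            k = inserts[j]
            if k > 0 and src == "M":
                tc["mi"][j - 1] += 1
                tc["ii"][j - 1] += k - 1
                # Plan-7 forbids I->D; fold such pairs into I->M
                tc["im"][j - 1] += 1
            else:
                # k>0 with src == "D" would need D->I (forbidden); fold to D->dst
                key = (src + dst).lower()
                if key in tc:
                    tc[key][j - 1] += 1

    def _em(counts):
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            p = (counts + pseudocount * q) / (tot + pseudocount)
        # rows with no observations and no pseudocount fall back to background
        empty = (tot + pseudocount).ravel() == 0
        p[empty] = q
        return p

    match_em = _em(mcounts)
    insert_em = _em(icounts)

    # transition distributions with additive pseudocounts, then exit reservation
    pc = pseudocount
    t_mm = np.zeros(M); t_mi = np.zeros(M); t_md = np.zeros(M); t_me = np.zeros(M)
    t_im = np.zeros(M); t_ii = np.zeros(M)
    t_dm = np.zeros(M); t_dd = np.zeros(M)
    def _dist(counts, fallback):
        c = np.asarray(counts, float) + pc / len(counts)
        tot = c.sum()
        return c / tot if tot > 0 else np.asarray(fallback, float)

    for j in range(M - 1):
        m = _dist([tc["mm"][j], tc["mi"][j], tc["md"][j]], [1.0, 0.0, 0.0])
        t_mm[j], t_mi[j], t_md[j] = m * (1.0 - exit_prob)
        t_me[j] = exit_prob
        t_im[j], t_ii[j] = _dist([tc["im"][j], tc["ii"][j]], [0.5, 0.5])
        t_dm[j], t_dd[j] = _dist([tc["dm"][j], tc["dd"][j]], [0.5, 0.5])
    t_me[M - 1] = 1.0  # last match state must exit
    if M > 1:
        t_dm[M - 1] = 1.0  # D_M continues to E via its match neighbour; unused slot

    # Local entry: half the mass on the first match state, the rest spread
    # uniformly over later states. A 5' truncation (late entry) then costs
    # about as much as a 3' truncation (early exit at exit_prob), keeping
    # local alignment endpoints unbiased between the two model ends.
    if M == 1:
        entry = np.ones(1)
    else:
        entry = np.full(M, 0.5 / (M - 1))
        entry[0] = 0.5

    hmm = ProfileHMM(
        match_emissions=match_em,
        insert_emissions=insert_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_me=t_me,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        entry=entry,
        background=q,
    )
    # normalize the unused D_M slot so validation sees proper distributions
    hmm.validate()
    return hmm


def background_from_seqs(seqs, floor: float = 0.05) -> np.ndarray:
    """Base composition of a sequence collection, floored per base.

    The floor keeps E-value statistics stable on skewed synthetic
    backgrounds.
    """
    counts = np.zeros(4)
    for s in seqs:
        x = encode(s)
        for b in range(4):
            counts[b] += int((x == b).sum())
    total = counts.sum()
    q = counts / total if total > 0 else np.full(4, 0.25)
    q = np.maximum(q, floor)
    return q / q.sum()


# ---------------------------------------------------------------------------
# Numba DP kernels


@njit(cache=False)
def _vit_best(x, mlo, ilo, lentry, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Best local Viterbi bit score; O(M) memory. Returns (score, i_end, j_end)."""
    L = x.shape[0]
    M = mlo.shape[0] - 1
    vm_prev = np.full(M + 1, NEG)
    vi_prev = np.full(M + 1, NEG)
    vd_prev = np.full(M + 1, NEG)
    vm = np.full(M + 1, NEG)
    vi = np.full(M + 1, NEG)
    vd = np.full(M + 1, NEG)
    best = NEG
    bi = -1
    bj = -1
    for i in range(1, L + 1):
        c = x[i - 1]
        for j in range(1, M + 1):
            em = mlo[j, c]
            v = lentry[j]
            if j > 1:
                a = vm_prev[j - 1] + lmm[j - 1]
                if a > v:
                    v = a
                a = vi_prev[j - 1] + lim[j - 1]
                if a > v:
                    v = a
                a = vd_prev[j - 1] + ldm[j - 1]
                if a > v:
                    v = a
            vm[j] = em + v
            s = vm[j] + lme[j]
            if s > best:
                best = s
                bi = i
                bj = j
        for j in range(2, M + 1):
            a = vm[j - 1] + lmd[j - 1]
            b = vd[j - 1] + ldd[j - 1]
            vd[j] = a if a > b else b
        for j in range(1, M):
            a = vm_prev[j] + lmi[j]
            b = vi_prev[j] + lii[j]
            vi[j] = ilo[j, c] + (a if a > b else b)
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
        for j in range(M + 1):
            vm[j] = NEG
            vi[j] = NEG
            vd[j] = NEG
    return best, bi, bj


@njit(cache=False)
def _vit_trace(x, mlo, ilo, lentry, lmm, lmi, lmd, lim, lii, ldm, ldd, lme):
    """Full Viterbi matrices + backpointers on a (short) window."""
    L = x.shape[0]
    M = mlo.shape[0] - 1
    VM = np.full((L + 1, M + 1), NEG)
    VI = np.full((L + 1, M + 1), NEG)
    VD = np.full((L + 1, M + 1), NEG)
    # backpointers: M: 0=entry 1=MM 2=IM 3=DM; I: 0=MI 1=II; D: 0=MD 1=DD
    PM = np.zeros((L + 1, M + 1), dtype=np.int8)
    PI = np.zeros((L + 1, M + 1), dtype=np.int8)
    PD = np.zeros((L + 1, M + 1), dtype=np.int8)
    for i in range(1, L + 1):
        c = x[i - 1]
        for j in range(1, M + 1):
            em = mlo[j, c]
            v = lentry[j]
            p = 0
            if j > 1:
                a = VM[i - 1, j - 1] + lmm[j - 1]
                if a > v:
                    v = a
                    p = 1
                a = VI[i - 1, j - 1] + lim[j - 1]
                if a > v:
                    v = a
                    p = 2
                a = VD[i - 1, j - 1] + ldm[j - 1]
                if a > v:
                    v = a
                    p = 3
            VM[i, j] = em + v
            PM[i, j] = p
        for j in range(2, M + 1):
            a = VM[i, j - 1] + lmd[j - 1]
            b = VD[i, j - 1] + ldd[j - 1]
            if a >= b:
                VD[i, j] = a
                PD[i, j] = 0
            else:
                VD[i, j] = b
                PD[i, j] = 1
        for j in range(1, M):
            a = VM[i - 1, j] + lmi[j]
            b = VI[i - 1, j] + lii[j]
            if a >= b:
                VI[i, j] = ilo[j, c] + a
                PI[i, j] = 0
            else:
                VI[i, j] = ilo[j, c] + b
                PI[i, j] = 1
    return VM, VI, VD, PM, PI, PD


# ---------------------------------------------------------------------------
# Search API


def viterbi_best_score(hmm: ProfileHMM, target: str) -> float:
    """Best local Viterbi bit score on one strand of one target."""
    if not target:
        raise ValueError("empty target")
    tables = hmm._tables()
    best, _, _ = _vit_best(encode(target), *tables)
    return float(best)


def _traceback(hmm, x_window, tables, i_end, j_end):
    """Trace the best path ending at (i_end, j_end) within the window."""
    VM, VI, VD, PM, PI, PD = _vit_trace(x_window, *tables)
    path = []
    i, j, state = i_end, j_end, "M"
    start_i = None
    while True:
        path.append((state, j))
        if state == "M":
            p = PM[i, j]
            if p == 0:
                start_i = i
                break
            i, j, state = i - 1, j - 1, ("M", "M", "I", "D")[p]
        elif state == "I":
            p = PI[i, j]
            i, state = i - 1, ("M" if p == 0 else "I")
        else:  # D (silent)
            p = PD[i, j]
            j, state = j - 1, ("M" if p == 0 else "D")
    path.reverse()
    return path, start_i, float(VM[i_end, j_end])


def viterbi_local(
    hmm: ProfileHMM,
    target: str,
    target_id: str = "target",
    bit_threshold: float | None = None,
    e_threshold: float | None = None,
    max_hits: int = 128,
    strand: str = "+",
) -> list[HmmHit]:
    """Best non-overlapping local matches on one strand of one target.

    Hits are collected greedily: the single best local alignment is accepted,
    its span is masked, and the target is rescanned until no alignment clears
    the threshold. If ``e_threshold`` is given the model must be calibrated
    (and ``n_eff`` set); otherwise ``bit_threshold`` (default 0 bits) is used.
    Coordinates in the returned hits are 1-based inclusive along ``target``
    as given (the caller maps minus-strand scans back to plus coordinates).
    """
    if not target:
        raise ValueError("empty target")
    if e_threshold is not None:
        if not hmm.calibrated or hmm.n_eff is None:
            raise ModelError("E-value thresholding requires a calibrated model")
        bit_min = score_for_evalue(e_threshold, hmm.mu, hmm.lam, hmm.n_eff)
    else:
        bit_min = 0.0 if bit_threshold is None else bit_threshold
    tables = hmm._tables()
    x = encode(target)
    M = hmm.M
    hits: list[HmmHit] = []
    for _ in range(max_hits):
        best, i_end, j_end = _vit_best(x, *tables)
        if best < bit_min or i_end < 0:
            break
        window = 4 * M + 64
        end_bonus = tables[10][j_end]  # lme[j_end]
        while True:
            w0 = max(0, i_end - window)
            path, start_rel, vm_end = _traceback(
                hmm, x[w0:i_end], tables, i_end - w0, j_end
            )
            # the window must reproduce the global optimum at the end cell,
            # otherwise the true path starts before the window: widen
            if w0 == 0 or (start_rel > 1 and abs(vm_end + end_bonus - best) < 1e-6):
                break
            window *= 2
        start = w0 + start_rel - 1  # 0-based inclusive
        end = i_end  # 0-based exclusive
        aligned = ["-"] * M
        ti = start
        for state, j in path:
            if state == "M":
                aligned[j - 1] = target[ti]
                ti += 1
            elif state == "I":
                ti += 1
        ev = (
            e_value(best, hmm.mu, hmm.lam, hmm.n_eff)
            if hmm.calibrated and hmm.n_eff is not None
            else math.inf
        )
        hits.append(
            HmmHit(
                target_id=target_id,
                S=start + 1,
                E=end,
                strand=strand,
                bit_score=float(best),
                e_value=float(ev),
                path=[f"{s}{j}" for s, j in path],
                aligned_row="".join(aligned),
            )
        )
        x[start:end] = _MASK_CODE
    return hits


def search_sequence(
    hmm: ProfileHMM,
    target: str,
    target_id: str = "target",
    e_threshold: float | None = None,
    bit_threshold: float | None = None,
    both_strands: bool = True,
) -> list[HmmHit]:
    """Scan one target on both strands; minus-strand coordinates are mapped
    back to the plus strand (S <= E retained, strand set to "-")."""
    hits = viterbi_local(
        hmm, target, target_id,
        bit_threshold=bit_threshold, e_threshold=e_threshold, strand="+",
    )
    if both_strands:
        L = len(target)
        for h in viterbi_local(
            hmm, revcomp(target), target_id,
            bit_threshold=bit_threshold, e_threshold=e_threshold, strand="-",
        ):
            s0, e0 = h.S - 1, h.E  # 0-based half-open on the reverse strand
            h.S, h.E = L - e0 + 1, L - s0
            hits.append(h)
    hits.sort(key=lambda h: (h.S, h.E, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Forward (reference implementation, O(L*M) Python; used at small scale)


def forward_local(hmm: ProfileHMM, target: str) -> float:
    """Total local log-odds score in bits: log2 of the sum over all local
    paths (all start/end points) of path-probability / background odds.

    Always >= the Viterbi score for the same target. Quadratic-time pure
    Python; intended for validation and small inputs.
    """
    if not target:
        raise ValueError("empty target")
    mlo, ilo, lentry, lmm, lmi, lmd, lim, lii, ldm, ldd, lme = hmm._tables()
    x = encode(target)
    L, M = len(x), hmm.M

    def lse(*vals):
        mx = max(vals)
        if mx <= NEG / 2:
            return NEG
        return mx + math.log2(sum(2.0 ** (v - mx) for v in vals))

    FM = np.full((L + 1, M + 1), NEG)
    FI = np.full((L + 1, M + 1), NEG)
    FD = np.full((L + 1, M + 1), NEG)
    total = NEG
    for i in range(1, L + 1):
        c = x[i - 1]
        for j in range(1, M + 1):
            terms = [lentry[j]]
            if j > 1:
                terms += [
                    FM[i - 1, j - 1] + lmm[j - 1],
                    FI[i - 1, j - 1] + lim[j - 1],
                    FD[i - 1, j - 1] + ldm[j - 1],
                ]
            FM[i, j] = mlo[j, c] + lse(*terms)
            total = lse(total, FM[i, j] + lme[j])
        for j in range(2, M + 1):
            FD[i, j] = lse(FM[i, j - 1] + lmd[j - 1], FD[i, j - 1] + ldd[j - 1])
        for j in range(1, M):
            FI[i, j] = ilo[j, c] + lse(FM[i - 1, j] + lmi[j], FI[i - 1, j] + lii[j])
    return float(total)


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    sample_len: int = 200,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float]:
    """Fit Gumbel (mu, lambda) to best-per-sequence Viterbi bit scores on
    i.i.d. background sequences drawn from the model background. Sets
    ``hmm.mu`` / ``hmm.lam`` and returns them. Deterministic given seed."""
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    tables = hmm._tables()
    scores = np.empty(n_samples)
    for k in range(n_samples):
        seq = random_seq(rng, sample_len, hmm.background)
        # one strand per sample; the strand multiplicity of a real search
        # enters through N_eff instead
        s, _, _ = _vit_best(encode(seq), *tables)
        scores[k] = s
    if np.std(scores) < 1e-12:
        raise CalibrationError("degenerate (zero-variance) score distribution")
    loc, scale = gumbel_r.fit(scores)
    hmm.mu = float(loc)
    hmm.lam = float(1.0 / scale)
    return hmm.mu, hmm.lam


def e_value(bit_score: float, mu: float, lam: float, n_eff: float) -> float:
    """E = N_eff * P(best background score >= s) under the fitted Gumbel."""
    p = -math.expm1(-math.exp(-lam * (bit_score - mu)))
    return n_eff * p


def score_for_evalue(e: float, mu: float, lam: float, n_eff: float) -> float:
    """Inverse of :func:`e_value`: minimum bit score with E-value <= e."""
    p = min(max(e / n_eff, 1e-300), 1.0 - 1e-12)
    return mu - math.log(-math.log1p(-p)) / lam


# ---------------------------------------------------------------------------
# Realignment of hits into the next cycle's alignment


def hits_to_alignment(hits) -> Alignment:
    """Place each hit's residues in model-column coordinates (M columns).

    Deletions appear as gaps, insertions are dropped; model columns outside
    the local alignment span are gap-filled. The result feeds build_hmm for
    the next refinement cycle.
    """
    hits = list(hits)
    if not hits:
        raise ModelError("no hits to align; iteration must stop")
    width = len(hits[0].aligned_row)
    if any(len(h.aligned_row) != width for h in hits):
        raise ModelError("hits aligned against different models")
    ids = [f"{h.target_id}/{h.S}-{h.E}({h.strand})" for h in hits]
    return Alignment(ids=ids, rows=[h.aligned_row for h in hits])
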