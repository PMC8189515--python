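"""Stochastic dosage-model contagion engine on layered graphs.

The model is an SIR elaboration with dose memory.  Each micro-step one
node (the *listener*) is drawn uniformly at random; one of its neighbors
(the *speaker*, pooled over all layers) is drawn uniformly.  An infected
speaker confers a random dose ~ Normal(dose_mean, dose_sd) truncated at
zero; a non-infected speaker confers a zero dose.  If hierarchy rules
are active and the speaker sits on a *higher* layer than the listener,
an infected speaker instead confers a dose exactly equal to the
listener's own threshold, guaranteeing an immediate switch.

Every node remembers its last ``T`` received doses (null doses
included).  Writing the cumulative dose ``D`` as the sum of that memory
and ``d*`` for the node's positive Gaussian threshold:

* a susceptible listener with ``D >= d*`` adopts (S -> I);
* an infected listener with ``D < d*`` abandons with probability ``r``
  per activation (I -> R); R is absorbing.

One *epoch* is ``N`` micro-steps (one expected activation per node).

Random-number contract (common random numbers): every run owns six
independent child streams of ``numpy.random.SeedSequence(master_seed)``
— seeding, thresholds, listener, speaker, dose, removal — and exactly
one variate per stream is consumed each micro-step whether or not it is
used.  Two graphs on the same node set simulated from the same master
seed therefore see identical node thresholds and identical attempted
transmission pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .layered import LayeredGraph
from .metrics import EnsembleSummary, time_to_consensus
from .seeding import SeedSpec, select_seeds

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "DosageParams",
    "NodeStateArray",
    "RunResult",
    "init_states",
    "micro_step",
    "run",
    "run_ensemble",
    "STATE_S",
    "STATE_I",
    "STATE_R",
]

STATE_S, STATE_I, STATE_R = 0, 1, 2

_STREAMS = ("seeding", "thresholds", "listener", "speaker", "dose", "removal")

CONSENSUS_LEVELS = (0.5, 0.74, 0.9, 1.0)


@dataclass(frozen=True)
class DosageParams:
    """All constants of the dosage model.

    Dose parameters are expressed in absolute dose units; the defaults
    are 0.5 and 0.25 times the nominal mean threshold of 1.  With
    ``si_mode`` the removal channel is switched off (``r`` treated as
    0), turning the dynamics into an SI consensus process.
    ``manager_override=False`` gives the flat-network ablation: the same
    edges with no hierarchical dose advantage.
    """

    T: int = 5
    r: float = 0.2
    threshold_mean: float = 1.0
    threshold_sd: float = 0.5
    dose_mean: float = 0.5
    dose_sd: float = 0.25
    manager_override: bool = True
    si_mode: bool = False
    max_micro_steps: int = 1_000_000
    early_stop_on_extinction: bool = True

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        if self.threshold_sd < 0 or self.dose_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.threshold_sd == 0 and self.threshold_mean <= 0:
            raise ValueError("degenerate thresholds must be positive")
        if self.dose_sd == 0 and self.dose_mean < 0:
            raise ValueError("degenerate doses must be >= 0")
        if self.max_micro_steps < 1:
            raise ValueError("max_micro_steps must be >= 1")

    @property
    def effective_r(self) -> float:
        return 0.0 if self.si_mode else self.r


@dataclass
class NodeStateArray:
    """Positional per-node simulation state.

    Arrays are indexed by position in ``node_order`` (node ids sorted
    ascending).  ``memory`` is a ring buffer of the last ``T`` doses per
    node with write pointer ``mem_ptr``.
    """

    node_order: list
    state: np.ndarray  # int8, values STATE_S/I/R
    thresholds: np.ndarray  # float64 > 0
    memory: np.ndarray  # float64 (N, T)
    mem_ptr: np.ndarray  # int64 (N,)

    def counts(self) -> tuple:
        return (
            int(np.sum(self.state == STATE_S)),
            int(np.sum(self.state == STATE_I)),
            int(np.sum(self.state == STATE_R)),
        )

    def cumulative_dose(self, pos: int) -> float:
        return float(self.memory[pos].sum())

    def copy(self) -> "NodeStateArray":
        return NodeStateArray(
            node_order=list(self.node_order),
            state=self.state.copy(),
            thresholds=self.thresholds.copy(),
            memory=self.memory.copy(),
            mem_ptr=self.mem_ptr.copy(),
        )


@dataclass
class RunResult:
    """Per-epoch S/I/R trajectory of one run plus derived scalars.

    Trajectories start at epoch 0 (initial condition).  ``peak_i`` is
    the maximum concurrent infected *count* tracked at micro-step
    resolution; ties resolve to the earliest step.  ``extinction_epoch``
    is the (ceiled) epoch at which I reached 0, or None.  After
    extinction (or SI consensus) the configuration is frozen, so
    trajectories may be exactly extended with their final row; ``pad``
    does this.
    """

    n_total: int
    epoch_len: int
    s: np.ndarray
    i: np.ndarray
    r: np.ndarray
    peak_i: int
    peak_epoch: int
    extinction_epoch: int | None
    steps: int
    events: list | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.i) - 1

    def pad(self, horizon_epochs: int) -> "RunResult":
        """Extend trajectories to ``horizon_epochs`` with the frozen tail."""
        cur = self.n_epochs
        if cur >= horizon_epochs:
            return self
        extra = horizon_epochs - cur
        return RunResult(
            n_total=self.n_total,
            epoch_len=self.epoch_len,
            s=np.concatenate([self.s, np.full(extra, self.s[-1])]),
            i=np.concatenate([self.i, np.full(extra, self.i[-1])]),
            r=np.concatenate([self.r, np.full(extra, self.r[-1])]),
            peak_i=self.peak_i,
            peak_epoch=self.peak_epoch,
            extinction_epoch=self.extinction_epoch,
            steps=self.steps,
            events=self.events,
        )


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    strict_positive: bool = False,
) -> np.ndarray:
    """Normal(mean, sd) samples truncated by resampling.

    ``strict_positive`` resamples non-positive draws (thresholds);
    otherwise negative draws are resampled and zero is allowed (doses).
    """
    if sd == 0.0:
        return np.full(size, float(mean))
    vals = rng.normal(mean, sd, size)
    bad = vals <= 0.0 if strict_positive else vals < 0.0
    while bad.any():
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = vals <= 0.0 if strict_positive else vals < 0.0
    return vals


def _spawn_streams(master_seed) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, children)
    }


def init_states(
    graph: LayeredGraph,
    params: DosageParams,
    seeds,
    rng_stream: np.random.Generator,
) -> NodeStateArray:
    """Sample thresholds (node-id order) and set seed nodes infected.

    Thresholds are Normal(threshold_mean, threshold_sd) resampled until
    strictly positive.  Memories start zero-filled, so seed nodes carry
    no dose support and face removal risk immediately.
    """
    order = graph.node_ids
    n = len(order)
    if n == 0:
        raise ValueError("graph is empty")
    seeds = set(seeds)
    if not seeds <= set(order):
        raise ValueError("seeds must be a subset of the graph's nodes")
    thr = truncated_normal(
        rng_stream,
        params.threshold_mean,
        params.threshold_sd,
        n,
        strict_positive=True,
    )
    state = np.zeros(n, dtype=np.int8)
    idx = {u: i for i, u in enumerate(order)}
    for u in seeds:
        state[idx[u]] = STATE_I
    return NodeStateArray(
        node_order=order,
        state=state,
        thresholds=thr,
        memory=np.zeros((n, params.T)),
        mem_ptr=np.zeros(n, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# single micro-step (reference implementation)
# ---------------------------------------------------------------------------

def _py_step(
    indptr, indices, layer, thr, state, mem, mem_ptr,
    T, r, override, u_l, u_s, dose_val, u_r,
):
    """One micro-step given the four per-step variates.

    Mutates the state arrays in place; returns
    ``(listener, speaker, dose, transition)`` with positional indices,
    ``speaker`` None for isolated listeners and ``transition`` one of
    None, "S->I", "I->R".
    """
    n = state.shape[0]
    l = min(int(u_l * n), n - 1)
    deg = indptr[l + 1] - indptr[l]
    speaker = None
    dose = 0.0
    if deg > 0:
        j = min(int(u_s * deg), deg - 1)
        speaker = int(indices[indptr[l] + j])
        if state[speaker] == STATE_I:
            if override and layer[speaker] > layer[l]:
                dose = float(thr[l])
            else:
                dose = float(dose_val)
    p = mem_ptr[l]
    mem[l, p] = dose
    mem_ptr[l] = (p + 1) % T
    d_cum = float(mem[l].sum())
    transition = None
    if state[l] == STATE_S:
        if d_cum >= thr[l]:
            state[l] = STATE_I
            transition = "S->I"
    elif state[l] == STATE_I:
        if d_cum < thr[l] and u_r < r:
            state[l] = STATE_R
            transition = "I->R"
    return l, speaker, dose, transition


def micro_step(
    state: NodeStateArray,
    graph: LayeredGraph,
    params: DosageParams,
    rng_streams: dict,
):
    """Advance one micro-step drawing variates from named streams.

    ``rng_streams`` must hold Generators under the keys "listener",
    "speaker", "dose" and "removal".  Returns the updated state (the
    same object, mutated) and the step record from :func:`_py_step`.
    """
    indptr, indices, layer, _ = graph.csr()
    u_l = rng_streams["listener"].random()
    u_s = rng_streams["speaker"].random()
    dose_val = float(
        truncated_normal(
            rng_streams["dose"], params.dose_mean, params.dose_sd, 1
        )[0]
    )
    u_r = rng_streams["removal"].random()
    rec = _py_step(
        indptr, indices, layer,
        state.thresholds, state.state, state.memory, state.mem_ptr,
        params.T, params.effective_r, params.manager_override,
        u_l, u_s, dose_val, u_r,
    )
    return state, rec


# ---------------------------------------------------------------------------
# chunked fast kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim_chunk(
    indptr, indices, layer, thr, state, mem, mem_ptr,
    n_s, n_i, n_r, t0, n_chunk,
    u_listener, u_speaker, dose_vals, u_removal,
    T, r, override,
    epoch_len, traj_s, traj_i, traj_r,
    peak, peak_step, max_steps,
):  # pragma: no cover - compiled; equivalence-tested against _py_step
    n = state.shape[0]
    status = 0
    t = t0
    for k in range(n_chunk):
        if t >= max_steps:
            status = 3
            break
        l = int(u_listener[k] * n)
        if l >= n:
            l = n - 1
        deg = indptr[l + 1] - indptr[l]
        dose = 0.0
        if deg > 0:
            j = int(u_speaker[k] * deg)
            if j >= deg:
                j = deg - 1
            s = indices[indptr[l] + j]
            if state[s] == 1:
                if override and layer[s] > layer[l]:
                    dose = thr[l]
                else:
                    dose = dose_vals[k]
        p = mem_ptr[l]
        mem[l, p] = dose
        mem_ptr[l] = (p + 1) % T
        d_cum = 0.0
        for q in range(T):
            d_cum += mem[l, q]
        if state[l] == 0:
            if d_cum >= thr[l]:
                state[l] = 1
                n_s -= 1
                n_i += 1
                if n_i > peak:
                    peak = n_i
                    peak_step = t
        elif state[l] == 1:
            if d_cum < thr[l] and u_removal[k] < r:
                state[l] = 2
                n_i -= 1
                n_r += 1
        t += 1
        if t % epoch_len == 0:
            e = t // epoch_len
            if e < traj_s.shape[0]:
                traj_s[e] = n_s
                traj_i[e] = n_i
                traj_r[e] = n_r
        if n_i == 0:
            status = 1
            break
        if r == 0.0 and n_s == 0:
            status = 2
            break
    return t, n_s, n_i, n_r, peak, peak_step, status


def _sim_chunk_py(
    indptr, indices, layer, thr, state, mem, mem_ptr,
    n_s, n_i, n_r, t0, n_chunk,
    u_listener, u_speaker, dose_vals, u_removal,
    T, r, override,
    epoch_len, traj_s, traj_i, traj_r,
    peak, peak_step, max_steps,
    events=None,
):
    """Pure-Python chunk loop over :func:`_py_step` (reference path)."""
    t = t0
    status = 0
    for k in range(n_chunk):
        if t >= max_steps:
            status = 3
            break
        l, speaker, dose, transition = _py_step(
            indptr, indices, layer, thr, state, mem, mem_ptr,
            T, r, override,
            u_listener[k], u_speaker[k], dose_vals[k], u_removal[k],
        )
        if transition == "S->I":
            n_s -= 1
            n_i += 1
            if n_i > peak:
                peak = n_i
                peak_step = t
        elif transition == "I->R":
            n_i -= 1
            n_r += 1
        if events is not None and transition is not None:
            events.append((t, l, speaker, dose, transition))
        t += 1
        if t % epoch_len == 0:
            e = t // epoch_len
            if e < traj_s.shape[0]:
                traj_s[e] = n_s
                traj_i[e] = n_i
                traj_r[e] = n_r
        if n_i == 0:
            status = 1
            break
        if r == 0.0 and n_s == 0:
            status = 2
            break
    return t, n_s, n_i, n_r, peak, peak_step, status


def _run_with_streams(
    graph: LayeredGraph,
    params: DosageParams,
    seeds,
    streams: dict,
    backend: str = "numba",
    record_events: bool = False,
) -> RunResult:
    indptr, indices, layer, _ = graph.csr()
    n = len(layer)
    state_arr = init_states(graph, params, seeds, streams["thresholds"])
    epoch_len = n
    max_steps = params.max_micro_steps
    max_epochs = math.ceil(max_steps / epoch_len)
    traj_s = np.full(max_epochs + 1, -1, dtype=np.int64)
    traj_i = np.full(max_epochs + 1, -1, dtype=np.int64)
    traj_r = np.full(max_epochs + 1, -1, dtype=np.int64)
    n_s, n_i, n_r = state_arr.counts()
    traj_s[0], traj_i[0], traj_r[0] = n_s, n_i, n_r
    peak, peak_step = n_i, 0
    events: list | None = [] if record_events else None
    if record_events:
        backend = "python"
    use_numba = backend == "numba" and _HAVE_NUMBA
    chunk_fn = _sim_chunk if use_numba else _sim_chunk_py
    t = 0
    status = 1 if n_i == 0 else 0
    chunk = 16384
    while status == 0 and t < max_steps:
        k = min(chunk, max_steps - t)
        u_l = streams["listener"].random(k)
        u_s = streams["speaker"].random(k)
        dv = truncated_normal(
            streams["dose"], params.dose_mean, params.dose_sd, k
        )
        u_r = streams["removal"].random(k)
        args = (
            indptr, indices, layer,
            state_arr.thresholds, state_arr.state,
            state_arr.memory, state_arr.mem_ptr,
            n_s, n_i, n_r, t, k,
            u_l, u_s, dv, u_r,
            params.T, params.effective_r, params.manager_override,
            epoch_len, traj_s, traj_i, traj_r,
            peak, peak_step, max_steps,
        )
        if use_numba:
            t, n_s, n_i, n_r, peak, peak_step, status = chunk_fn(*args)
        else:
            t, n_s, n_i, n_r, peak, peak_step, status = chunk_fn(
                *args, events=events
            )
        chunk = min(chunk * 4, 1 << 18)
    # complete the trajectory: fill the partial final epoch, then trim/pad
    final_e = math.ceil(t / epoch_len)
    for e in range(final_e + 1):
        if traj_s[e] < 0:
            traj_s[e], traj_i[e], traj_r[e] = n_s, n_i, n_r
    end = final_e
    if not params.early_stop_on_extinction:
        # the post-freeze tail is exactly constant; extend to the horizon
        for e in range(final_e + 1, max_epochs + 1):
            traj_s[e], traj_i[e], traj_r[e] = n_s, n_i, n_r
        end = max_epochs
    extinction = final_e if (status == 1 and len(seeds) > 0) else None
    return RunResult(
        n_total=n,
        epoch_len=epoch_len,
        s=traj_s[: end + 1].copy(),
        i=traj_i[: end + 1].copy(),
        r=traj_r[: end + 1].copy(),
        peak_i=int(peak),
        peak_epoch=int(peak_step // epoch_len),
        extinction_epoch=extinction,
        steps=int(t),
        events=events,
    )


def run(
    graph: LayeredGraph,
    params: DosageParams,
    seeds,
    rng_master_seed,
    backend: str = "numba",
    record_events: bool = False,
) -> RunResult:
    """Simulate one run, fully reproducible from ``rng_master_seed``."""
    streams = _spawn_streams(rng_master_seed)
    return _run_with_streams(
        graph, params, seeds, streams,
        backend=backend, record_events=record_events,
    )


def run_ensemble(
    graph: LayeredGraph,
    params: DosageParams,
    seed_spec: SeedSpec,
    n_runs: int,
    master_seeds,
    backend: str = "numba",
    allow_duplicate_seeds: bool = False,
) -> EnsembleSummary:
    """Independent replicates with per-run seed selection and CRN streams.

    Each master seed spawns the run's six variate streams; the seeding
    stream re-selects seed nodes per run (deterministic strategies give
    identical sets every run).  Duplicate master seeds defeat the
    common-random-number pairing and are rejected unless explicitly
    allowed.
    """
    master_seeds = list(master_seeds)
    if n_runs < 1 or len(master_seeds) != n_runs:
        raise ValueError("need n_runs >= 1 master seeds, one per run")
    if not allow_duplicate_seeds and len(set(master_seeds)) != n_runs:
        raise ValueError("duplicate master seeds break the CRN contract")
    n = graph.n_nodes
    horizon = math.ceil(params.max_micro_steps / n)
    i_max = np.empty(n_runs)
    peak_epoch = np.empty(n_runs)
    extinction = np.full(n_runs, np.nan)
    sum_s = np.zeros(horizon + 1)
    sum_i = np.zeros(horizon + 1)
    sum_r = np.zeros(horizon + 1)
    sum_surv = np.zeros(horizon + 1)
    consensus = (
        {lvl: np.full(n_runs, np.nan) for lvl in CONSENSUS_LEVELS}
        if params.si_mode
        else {}
    )
    for j, seed in enumerate(master_seeds):
        streams = _spawn_streams(seed)
        seeds_j = select_seeds(graph, seed_spec, streams["seeding"])
        res = _run_with_streams(graph, params, seeds_j, streams, backend)
        padded = res.pad(horizon)
        i_max[j] = res.peak_i / n
        peak_epoch[j] = res.peak_epoch
        if res.extinction_epoch is not None:
            extinction[j] = res.extinction_epoch
        sum_s += padded.s
        sum_i += padded.i
        sum_r += padded.r
        if res.peak_i > 0:
            sum_surv += padded.i / res.peak_i
        for lvl in consensus:
            tt = time_to_consensus(padded, lvl)
            if tt is not None:
                consensus[lvl][j] = tt
    return EnsembleSummary(
        n_runs=n_runs,
        n_total=n,
        i_max=i_max,
        peak_epoch=peak_epoch,
        extinction_epoch=extinction,
        mean_s=sum_s / n_runs,
        mean_i=sum_i / n_runs,
        mean_r=sum_r / n_runs,
        mean_survival=sum_surv / n_runs,
        consensus_epochs=consensus,
    )
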