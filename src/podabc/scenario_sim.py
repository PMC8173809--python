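"""Demographic scenarios of Podolian cattle colonization and their simulation.

Six built-in scenarios describe how five grouped cattle populations —
Asian indicine (IND), non-Podolian European taurine (NPT), Italian Podolian
(ITP), Balkan Podolian (BKP) and South-East Mediterranean Podolian (SEP) —
descend from a common ancestor.  All six share a backbone: a deep
taurine/indicine split (t3), independent domestication bottlenecks (tdt,
tdi), an indicine admixture pulse into the Podolian ancestor (ta), a split
of the non-Podolian taurine lineage (tD), and a Balkan/South-East Podolian
split (t1).  They differ in

* the *route* by which the Italian Podolian group formed at ta1 —
  Mediterranean (split from SEP, with a founder-effect size reduction),
  Balkan (split from BKP), or admixture between BKP and SEP with
  proportion r — and
* the *set*: in set 1 (two colonization waves, scenarios 1-3) the
  non-Podolian taurine split tD predates the indicine admixture ta;
  in set 2 (one wave, scenarios 4-6) it postdates it, so the non-Podolian
  taurine lineage shares the indicine pulse.

Times are in generations before present, sizes in diploid individuals.
Loci are unlinked (the observed data these scenarios emulate are LD-pruned),
so there is no recombination machinery; SNP-chip ascertainment is emulated
by conditioning each locus on a pooled minor-allele-frequency floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _coalescent
from .genotype_io import GenotypeDataset, from_arrays

# population indices used by the engine
POPS = ("IND", "NPT", "ITP", "BKP", "SEP", "ANC")
_PIDX = {p: i for i, p in enumerate(POPS)}

#: breed code -> group label for simulated datasets
SIM_GROUPS = {
    "IND": "indicine",
    "NPT": "nonpodolian_taurine",
    "ITP": "italian_podolian",
    "BKP": "balkan_podolian",
    "SEP": "se_podolian",
}

#: default diploid sample sizes per population
DEFAULT_SAMPLES = {"IND": 30, "NPT": 40, "ITP": 49, "BKP": 48, "SEP": 43}

PARAM_NAMES = (
    "N1", "N2", "N3", "N4", "N4b", "N5", "N5b",
    "t3", "tdt", "tdi", "tD", "ta", "t1", "ta1",
    "r", "ra",
    "N_dom_taur", "dur_dom_taur", "N_dom_ind", "dur_dom_ind",
    "N_founder", "dur_founder",
)


@dataclass(frozen=True)
class ParamVector:
    """One draw of the demographic parameters.

    N1/N2/N4/N4b/N5 are the present-day sizes of IND/NPT/BKP/ITP/SEP; N5b is
    the Podolian (second-wave) ancestor between t1 and the taurine
    domestication; N3 the deep taurine ancestor and root.  ``r`` is the BKP
    contribution to an admixture-formed ITP, ``ra`` the indicine fraction of
    the pulse at ta.  Domestication and founder bottlenecks have a size and
    a duration in generations.
    """

    N1: float; N2: float; N3: float; N4: float; N4b: float
    N5: float; N5b: float
    t3: float; tdt: float; tdi: float; tD: float; ta: float
    t1: float; ta1: float
    r: float; ra: float
    N_dom_taur: float; dur_dom_taur: float
    N_dom_ind: float; dur_dom_ind: float
    N_founder: float; dur_founder: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def validate(self, set_id: int) -> None:
        d = self.as_dict()
        if any(v <= 0 for k, v in d.items() if k not in ("r", "ra")):
            raise ValueError("all sizes and times must be positive")
        if not (0.0 <= self.r <= 1.0 and 0.0 <= self.ra <= 1.0):
            raise ValueError("admixture proportions must lie in [0, 1]")
        if not self.t3 > max(self.tdt, self.tdi):
            raise ValueError("t3 must predate both domestications")
        chain = ((self.tdt, self.tD, self.ta, self.t1, self.ta1)
                 if set_id == 1 else
                 (self.tdt, self.ta, self.tD, self.t1, self.ta1))
        if not all(x >= y for x, y in zip(chain, chain[1:])):
            raise ValueError(f"time ordering violated for set {set_id}: {chain}")


@dataclass(frozen=True)
class Event:
    """One demographic event; ``time``/``size``/``prop`` entries may be
    parameter names, ``-name`` (negated) or numbers, summed at bind time."""

    kind: str                       # sample | size_change | split | admixture
    time: tuple = (0.0,)
    pop: str = ""                   # sample / size_change subject
    n: int = 0                      # sample size (diploids)
    size: object = None             # size_change target size
    derived: str = ""               # split
    ancestral: str = ""             # split
    target: str = ""                # admixture
    source_a: str = ""              # admixture (prob = prop)
    source_b: str = ""              # admixture (prob = 1 - prop)
    prop: object = 1.0


def _bind(terms, params: dict) -> float:
    if not isinstance(terms, tuple):
        terms = (terms,)
    total = 0.0
    for t in terms:
        if isinstance(t, str):
            if t.startswith("-"):
                total -= params[t[1:]]
            else:
                total += params[t]
        else:
            total += float(t)
    return total


@dataclass(frozen=True)
class ScenarioSpec:
    """A colonization scenario: id, wave set, route and its event list."""

    scenario_id: int
    set_id: int                     # 1 = two waves, 2 = one wave
    route: str                      # mediterranean | balkan | admixture
    events: tuple = ()

    def compile(self, params: ParamVector, sample_sizes: dict):
        """Bind parameter values and return kernel-ready event arrays."""
        p = params.as_dict()
        samp = np.zeros(len(POPS), dtype=np.int64)
        init_N = np.ones(len(POPS), dtype=np.float64)
        rows = []
        for ev in self.events:
            t = max(_bind(ev.time, p), 0.0)
            if ev.kind == "sample":
                n = sample_sizes.get(ev.pop, ev.n)
                samp[_PIDX[ev.pop]] = 2 * n
            elif ev.kind == "size_change":
                if t == 0.0:
                    init_N[_PIDX[ev.pop]] = _bind(ev.size, p)
                else:
                    rows.append((t, 0, _PIDX[ev.pop], 0, 0, _bind(ev.size, p)))
            elif ev.kind == "split":
                rows.append((t, 1, _PIDX[ev.derived], _PIDX[ev.ancestral],
                             _PIDX[ev.ancestral], 1.0))
            elif ev.kind == "admixture":
                rows.append((t, 1, _PIDX[ev.target], _PIDX[ev.source_a],
                             _PIDX[ev.source_b], _bind(ev.prop, p)))
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
        rows.sort(key=lambda x: x[0])
        ev_time = np.array([x[0] for x in rows], dtype=np.float64)
        ev_type = np.array([x[1] for x in rows], dtype=np.int64)
        ev_a = np.array([x[2] for x in rows], dtype=np.int64)
        ev_b = np.array([x[3] for x in rows], dtype=np.int64)
        ev_c = np.array([x[4] for x in rows], dtype=np.int64)
        ev_x = np.array([x[5] for x in rows], dtype=np.float64)
        return samp, init_N, (ev_time, ev_type, ev_a, ev_b, ev_c, ev_x)

    def validate_coalescence(self) -> None:
        """Check that every sampled population's lineages can reach a single
        root population through the event list."""
        reach = {ev.pop for ev in self.events if ev.kind == "sample"}
        for ev in self.events:      # events are ordered backward in time
            if ev.kind == "split" and ev.derived in reach:
                reach.discard(ev.derived)
                reach.add(ev.ancestral)
            elif ev.kind == "admixture" and ev.target in reach:
                reach.discard(ev.target)
                if _bind(ev.prop, {k: 0.5 for k in PARAM_NAMES}) > 0:
                    reach.add(ev.source_a)
                reach.add(ev.source_b)
        if len(reach) != 1:
            raise ValueError(
                f"scenario {self.scenario_id}: lineages end in populations "
                f"{sorted(reach)}; they must coalesce into one root")

    def to_yaml(self) -> str:
        def enc(v):
            return list(v) if isinstance(v, tuple) else v
        doc = {
            "scenario_id": self.scenario_id,
            "set_id": self.set_id,
            "route": self.route,
            "events": [
                {k: enc(v) for k, v in vars(ev).items()
                 if v not in ("", 0, None) or k == "kind"}
                for ev in self.events
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ScenarioSpec":
        doc = yaml.safe_load(text)
        events = []
        for e in doc["events"]:
            e = dict(e)
            for key in ("time",):
                if key in e and isinstance(e[key], list):
                    e[key] = tuple(e[key])
            events.append(Event(**e))
        return ScenarioSpec(doc["scenario_id"], doc["set_id"], doc["route"],
                            tuple(events))


def _backbone(route: str) -> tuple:
    """Event list shared by both sets; set membership only changes the
    ordering constraints on (tD, ta), not the event vocabulary."""
    ev = [
        Event("sample", pop="IND", n=DEFAULT_SAMPLES["IND"]),
        Event("sample", pop="NPT", n=DEFAULT_SAMPLES["NPT"]),
        Event("sample", pop="ITP", n=DEFAULT_SAMPLES["ITP"]),
        Event("sample", pop="BKP", n=DEFAULT_SAMPLES["BKP"]),
        Event("sample", pop="SEP", n=DEFAULT_SAMPLES["SEP"]),
        Event("size_change", time=(0.0,), pop="IND", size="N1"),
        Event("size_change", time=(0.0,), pop="NPT", size="N2"),
        Event("size_change", time=(0.0,), pop="ITP", size="N4b"),
        Event("size_change", time=(0.0,), pop="BKP", size="N4"),
        Event("size_change", time=(0.0,), pop="SEP", size="N5"),
        Event("size_change", time=(0.0,), pop="ANC", size="N5b"),
    ]
    if route == "mediterranean":
        # founder effect immediately after the founding, forward in time
        ev += [Event("size_change", time=("ta1", "-dur_founder"), pop="ITP",
                     size="N_founder"),
               Event("split", time=("ta1",), derived="ITP", ancestral="SEP")]
    elif route == "balkan":
        ev += [Event("split", time=("ta1",), derived="ITP", ancestral="BKP")]
    elif route == "admixture":
        ev += [Event("admixture", time=("ta1",), target="ITP",
                     source_a="BKP", source_b="SEP", prop="r")]
    else:
        raise ValueError(f"unknown route {route!r}")
    ev += [
        Event("split", time=("t1",), derived="BKP", ancestral="ANC"),
        Event("split", time=("t1",), derived="SEP", ancestral="ANC"),
        Event("admixture", time=("ta",), target="ANC",
              source_a="IND", source_b="ANC", prop="ra"),
        Event("split", time=("tD",), derived="NPT", ancestral="ANC"),
        Event("size_change", time=("tdt",), pop="ANC", size="N_dom_taur"),
        Event("size_change", time=("tdt", "dur_dom_taur"), pop="ANC",
              size="N3"),
        Event("size_change", time=("tdi",), pop="IND", size="N_dom_ind"),
        Event("size_change", time=("tdi", "dur_dom_ind"), pop="IND",
              size="N3"),
        Event("split", time=("t3",), derived="IND", ancestral="ANC"),
    ]
    return tuple(ev)


def build_builtin_scenarios() -> list:
    """The six colonization scenarios: {1,2,3} x two waves, {4,5,6} x one
    wave, each set covering the Mediterranean, Balkan and admixture routes."""
    routes = ("mediterranean", "balkan", "admixture")
    specs = []
    for set_id in (1, 2):
        for k, route in enumerate(routes):
            sid = 3 * (set_id - 1) + k + 1
            specs.append(ScenarioSpec(sid, set_id, route, _backbone(route)))
    for s in specs:
        s.validate_coalescence()
    return specs


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors plus set-specific orderings on the time
    parameters, enforced by rejection.

    The taurine domestication time tdt carries the internal calibration
    Uniform(3600, 7800) generations.  Remaining defaults are package
    choices (see docs/methods.md) and can be overridden from configuration.
    """

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))

    #: descending time chains; every adjacent pair must satisfy left >= right
    CHAINS = {1: ("tdt", "tD", "ta", "t1", "ta1"),
              2: ("tdt", "ta", "tD", "t1", "ta1")}

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {k}: lower {lo} >= upper {hi}")

    def chain(self, set_id: int):
        return self.CHAINS[set_id]


_DEFAULT_BOUNDS = {
    "N1": (100.0, 50_000.0), "N2": (100.0, 50_000.0),
    "N3": (100.0, 50_000.0), "N4": (100.0, 50_000.0),
    "N4b": (100.0, 50_000.0), "N5": (100.0, 50_000.0),
    "N5b": (100.0, 50_000.0),
    "t3": (80_000.0, 120_000.0),
    "tdt": (3600.0, 7800.0),
    "tdi": (1600.0, 7800.0),
    "tD": (10.0, 7800.0), "ta": (10.0, 7800.0),
    "t1": (10.0, 7800.0), "ta1": (10.0, 7800.0),
    "r": (0.05, 0.95), "ra": (0.05, 0.5),
    "N_dom_taur": (50.0, 2000.0), "dur_dom_taur": (2.0, 50.0),
    "N_dom_ind": (50.0, 2000.0), "dur_dom_ind": (2.0, 50.0),
    "N_founder": (50.0, 2000.0), "dur_founder": (2.0, 50.0),
}


def draw_params(priors: PriorSpec, scenario: ScenarioSpec,
                rng: np.random.Generator, _block: int = 256) -> ParamVector:
    """Draw one parameter vector satisfying the scenario set's time ordering.

    Unconstrained parameters — including the tdt calibration and t3 — are
    drawn once from their uniforms, so their marginals stay exactly uniform;
    the four chained times below tdt are rejection-sampled (in blocks) until
    they are ordered and do not exceed the drawn tdt.
    """
    vals = {k: float(rng.uniform(*priors.bounds[k])) for k in PARAM_NAMES}
    chain = priors.chain(scenario.set_id)
    tail = chain[1:]
    lo = np.array([priors.bounds[k][0] for k in tail])
    hi = np.array([priors.bounds[k][1] for k in tail])
    while True:
        draws = rng.uniform(lo, hi, size=(_block, len(tail)))
        ok = draws[:, 0] <= vals["tdt"]
        for a in range(len(tail) - 1):
            ok &= draws[:, a] >= draws[:, a + 1]
        hits = np.flatnonzero(ok)
        if hits.size:
            for k, v in zip(tail, draws[hits[0]]):
                vals[k] = float(v)
            pv = ParamVector(**vals)
            pv.validate(scenario.set_id)
            return pv


def midprior_params(scenario: ScenarioSpec,
                    priors: PriorSpec | None = None) -> ParamVector:
    """Deterministic representative parameters: each prior's midpoint, with
    the ordered time chain placed at the expected order statistics of its
    constrained uniforms (evenly spaced below the tdt midpoint)."""
    priors = priors or PriorSpec()
    vals = {k: 0.5 * (lo + hi) for k, (lo, hi) in priors.bounds.items()}
    chain = priors.chain(scenario.set_id)
    tdt = vals["tdt"]
    low = priors.bounds["ta1"][0]
    tail = chain[1:]
    m = len(tail)
    for j, name in enumerate(tail):
        frac = (m - j) / (m + 1.0)
        vals[name] = low + (tdt - low) * frac
    pv = ParamVector(**vals)
    pv.validate(scenario.set_id)
    return pv


# ---------------------------------------------------------------------------
# simulation front-end
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Problem-size knobs for one simulated dataset."""

    n_loci: int = 1000
    min_maf: float = 0.05
    sample_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    max_retry: int = 200

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")


def simulate_dataset(scenario: ScenarioSpec, params: ParamVector,
                     simcfg: SimConfig, rng: np.random.Generator
                     ) -> GenotypeDataset:
    """Simulate one chip-like genotype dataset under a scenario.

    Each locus is an independent coalescent genealogy carrying a single
    mutation, retained only if its pooled MAF reaches ``simcfg.min_maf``.
    Haploid lineages are paired consecutively into diploids (lineages within
    a population are exchangeable, so the pairing is immaterial).
    """
    params.validate(scenario.set_id)
    samp, init_N, ev = scenario.compile(params, simcfg.sample_sizes)
    seed = int(rng.integers(1, 2**31 - 1))
    hap, _tmrca, status = _coalescent.simulate_loci(
        samp, init_N, *ev, simcfg.n_loci, simcfg.min_maf,
        simcfg.max_retry, seed)
    if status == _coalescent.STATUS_RETRY_EXHAUSTED:
        raise RuntimeError(
            f"scenario {scenario.scenario_id}: a locus failed the MAF floor "
            f"{simcfg.min_maf} {simcfg.max_retry} times under params "
            f"{params.as_dict()}")
    if status == _coalescent.STATUS_NO_COALESCENCE:
        raise ValueError(f"scenario {scenario.scenario_id}: lineages cannot "
                         "coalesce; invalid event list")
    geno = (hap[:, 0::2] + hap[:, 1::2]).T.astype(np.int8)
    breeds = []
    for pop in POPS[:5]:
        breeds += [pop] * simcfg.sample_sizes.get(pop, 0)
    sample_ids = [f"{b}_{i:04d}" for i, b in enumerate(breeds)]
    ds = from_arrays(geno, breeds, SIM_GROUPS, sample_ids=sample_ids)
    ds.validate()
    return ds


def simulate_pods(scenario: ScenarioSpec, fixed_params: ParamVector,
                  n_replicates: int, simcfg: SimConfig,
                  rng: np.random.Generator) -> list:
    """Pseudo-observed datasets: fixed parameters, independent RNG streams."""
    return [simulate_dataset(scenario, fixed_params, simcfg, rng)
            for _ in range(n_replicates)]


def simulate_tmrca(scenario: ScenarioSpec, params: ParamVector,
                   sample_sizes: dict, n_replicates: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-locus times to the most recent common ancestor (generations),
    without ascertainment, for engine calibration checks."""
    samp, init_N, ev = scenario.compile(params, sample_sizes)
    seed = int(rng.integers(1, 2**31 - 1))
    _hap, tmrca, status = _coalescent.simulate_loci(
        samp, init_N, *ev, n_replicates, 0.0, 1, seed)
    if status < 0:
        raise ValueError("invalid scenario for tmrca simulation")
    return tmrca


def pairwise_tmrca(diploid_N: float, n_replicates: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Coalescence times of two haploid lineages in one constant-size
    population, via the same engine that generates datasets."""
    samp = np.array([2, 0, 0, 0, 0, 0], dtype=np.int64)
    init_N = np.full(6, float(diploid_N))
    empty_f = np.empty(0, dtype=np.float64)
    empty_i = np.empty(0, dtype=np.int64)
    seed = int(rng.integers(1, 2**31 - 1))
    _hap, tmrca, status = _coalescent.simulate_loci(
        samp, init_N, empty_f, empty_i, empty_i, empty_i, empty_i, empty_f,
        n_replicates, 0.0, 1, seed)
    assert status >= 0
    return tmrca


def load_run_config(path) -> tuple:
    """Read a YAML run configuration into (PriorSpec, SimConfig).

    Recognized keys (all optional): ``priors`` (parameter -> [low, high],
    merged over the defaults), ``n_loci``, ``min_maf``, ``sample_sizes``
    (population -> diploids), ``max_retry``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    bounds = dict(_DEFAULT_BOUNDS)
    for k, v in (doc.get("priors") or {}).items():
        if k not in bounds:
            raise ValueError(f"unknown prior parameter {k!r}")
        bounds[k] = (float(v[0]), float(v[1]))
    priors = PriorSpec(bounds)
    sizes = dict(DEFAULT_SAMPLES)
    sizes.update(doc.get("sample_sizes") or {})
    simcfg = SimConfig(n_loci=int(doc.get("n_loci", 1000)),
                       min_maf=float(doc.get("min_maf", 0.05)),
                       sample_sizes=sizes,
                       max_retry=int(doc.get("max_retry", 200)))
    return priors, simcfg


def hw_fixture(freqs, n_diploids: int, rng: np.random.Generator,
               breed: str = "POP", group: str = "other") -> GenotypeDataset:
    """Single-population Hardy-Weinberg fixture: genotypes ~ Binomial(2, p)."""
    freqs = np.asarray(freqs, dtype=float)
    geno = rng.binomial(2, freqs[None, :], size=(n_diploids, len(freqs)))
    return from_arrays(geno.astype(np.int8), [breed] * n_diploids,
                       {breed: group})
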