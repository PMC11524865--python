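"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, one per input family:

* a duplicated "fish-like" homology table — ortholog components whose
  zebrafish side may retain both post-duplication paralog copies, with
  Biomart-style confidence scores drawn per planted confidence class;
* per-cell-type expression tables with planted presence (Venn) structure,
  paralog co-expression on the duplicated side, and a replicated
  negative-binomial count matrix with planted differentially expressed genes;
* voltage-clamp recordings — capacitance from the NLC model on a 4 mV
  staircase plus Gaussian noise, optional displacement, and optional raw
  dual-sine current traces from the 3-element patch circuit.

All randomness flows from one root seed through hierarchically spawned
streams, so adding a generator never perturbs the others, and every generator
emits its ground truth next to the data.  Default parameter values emulate
the magnitudes of the study being modeled: ortholog class frequencies and
orphan rates that reproduce a published-style classification-table mix, presence-pattern
frequencies that reproduce the published Venn cell proportions, and the published OHC
parameter set for recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import (
    F1_HZ, F2_HZ, NLCParams, MotilityParams, PatchCircuit, Recording,
    SAMPLE_RATE_HZ, boltzmann_length, nlc_curve, simulate_two_sine_current,
)
from .homology import OrthologGroup

#: published OHC ground truth for recordings (slope factor 27 mV)
DEFAULT_NLC_TRUTH = NLCParams(qmax=1135.0, alpha=1.0 / 27.0, vhalf=-54.0, clin=7.9)
DEFAULT_MOTILITY_TRUTH = MotilityParams(lmax=0.35, alpha=1.0 / 27.0, vhalf=-54.0)

DEFAULT_CELL_SPECIES = {"zHC": "a", "zSC": "a", "IHC": "b", "OHC": "b"}

#: presence-pattern frequencies over {zHC, IHC, OHC}, estimated from the
#: published Venn cell proportions over ~13.5k ortholog components
DEFAULT_PATTERN_PROBS = {
    frozenset({"zHC", "IHC", "OHC"}): 6659 / 13526,
    frozenset({"zHC", "IHC"}): 149 / 13526,
    frozenset({"zHC", "OHC"}): 322 / 13526,
    frozenset({"IHC", "OHC"}): 1594 / 13526,
    frozenset({"zHC"}): 2831 / 13526,
    frozenset({"IHC"}): 145 / 13526,
    frozenset({"OHC"}): 288 / 13526,
    frozenset(): 1538 / 13526,
}


@dataclass
class SimConfig:
    """Configuration for all three generators.  The seed is mandatory."""

    seed: int
    # homology graph
    n_ancestral_genes: int = 13500
    duplicate_retention: float = 0.27     # P(fish retains both paralog copies)
    mouse_duplication: float = 0.018      # P(mouse side has 2 genes)
    orphan_rate_a: float = 0.30           # fish genes with no mouse ortholog
    orphan_rate_b: float = 0.39           # mouse genes with no fish ortholog
    high_confidence_rate: float = 0.33    # pairs passing the confidence rule
    # expression
    cell_species: dict = field(default_factory=lambda: dict(DEFAULT_CELL_SPECIES))
    pattern_probs: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_PROBS))
    zsc_presence: float = 0.55            # P(zSC expressed | component)
    paralog_coexpression: float = 0.14    # P(second fish paralog also expressed)
    rpkm_log_mean: float = 1.5
    rpkm_log_sd: float = 1.5
    # counts / differential expression
    n_replicates: int = 5
    nb_dispersion: float = 0.1
    count_depth: float = 20.0             # counts per RPKM unit at size factor 1
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    # recordings
    nlc_truth: NLCParams = DEFAULT_NLC_TRUTH
    motility_truth: MotilityParams = DEFAULT_MOTILITY_TRUTH
    nlc_noise_sd: float = 0.05            # pF
    motility_noise_sd: float = 0.01       # um

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory; unseeded generation is not allowed")
        for name in ("duplicate_retention", "mouse_duplication", "orphan_rate_a",
                     "orphan_rate_b", "high_confidence_rate", "zsc_presence",
                     "paralog_coexpression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    def rng(self, stream: str) -> np.random.Generator:
        """Per-generator stream spawned from the root seed."""
        streams = {"homology": 0, "expression": 1, "recording": 2, "counts": 3}
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(streams))[streams[stream]]
        )


def _scores(rng, high: bool, n: int) -> dict:
    """Biomart-style confidence scores by planted class.

    High-confidence pairs satisfy (GOC >= 75 or WGA >= 75) and identity >= 50;
    low-confidence pairs fail at least one clause by construction.
    """
    if high:
        goc = 75.0 + 25.0 * rng.beta(2, 2, n)
        wga = np.where(rng.random(n) < 0.7, 75.0 + 25.0 * rng.beta(2, 2, n),
                       75.0 * rng.beta(2, 2, n))
        pid = 50.0 + 50.0 * rng.beta(2, 2, n)
    else:
        goc = 75.0 * rng.beta(2, 2, n)
        wga = 75.0 * rng.beta(2, 2, n)
        pid = np.where(rng.random(n) < 0.5, 50.0 * rng.beta(2, 2, n),
                       100.0 * rng.beta(2, 2, n))
        # a failed identity clause rescues rows whose GOC/WGA landed high
        pid = np.where((goc >= 75.0) | (wga >= 75.0), 50.0 * rng.beta(2, 2, n), pid)
    return {"goc": goc, "wga": wga, "pct_id": pid}


def generate_homology(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Homology pair table plus per-component truth labels.

    Returns ``(pairs, truth)``: pairs has the canonical columns of
    :func:`orthoexpress.homology.read_homology_table` output; truth has one
    row per ortholog component with its planted relationship class and
    members, plus orphan counts in ``truth.attrs``.
    """
    rng = config.rng("homology")
    n = config.n_ancestral_genes
    fish_two = rng.random(n) < config.duplicate_retention
    mouse_two = rng.random(n) < config.mouse_duplication
    pair_rows, truth_rows = [], []
    for i in range(n):
        za = [f"zg{i:06d}a"]
        if fish_two[i]:
            za.append(f"zg{i:06d}b")
        mm = [f"mg{i:06d}"]
        if mouse_two[i]:
            mm.append(f"mg{i:06d}x")
        n_a, n_b = len(za), len(mm)
        if n_a == 1 and n_b == 1:
            cls = "one-to-one"
        elif n_a == 1 or n_b == 1:
            cls = "one-to-many"
        else:
            cls = "many-to-many"
        truth_rows.append({"component": i, "relationship": cls,
                           "members_a": ";".join(za), "members_b": ";".join(mm)})
        for a in za:
            for b in mm:
                pair_rows.append({"gene_a": a, "gene_b": b, "component": i})
    pairs = pd.DataFrame(pair_rows)
    high = rng.random(len(pairs)) < config.high_confidence_rate
    scores_hi = _scores(rng, True, len(pairs))
    scores_lo = _scores(rng, False, len(pairs))
    for key in ("goc", "wga", "pct_id"):
        pairs[key] = np.where(high, scores_hi[key], scores_lo[key])
    pairs["homology_label"] = pairs["component"].map(
        dict(zip([t["component"] for t in truth_rows],
                 ["ortholog_" + t["relationship"].replace("-to-", "2").replace("-", "")
                  for t in truth_rows]))
    )
    pairs["high_confidence_truth"] = high
    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_orphans_a"] = int(round(
        config.orphan_rate_a / (1 - config.orphan_rate_a)
        * (pairs["gene_a"].nunique())))
    truth.attrs["n_orphans_b"] = int(round(
        config.orphan_rate_b / (1 - config.orphan_rate_b)
        * (pairs["gene_b"].nunique())))
    return pairs.drop(columns=["component"]), truth


def groups_from_truth(truth: pd.DataFrame) -> list[OrthologGroup]:
    """Materialize OrthologGroup objects directly from a homology truth table."""
    groups = []
    for row in truth.itertuples(index=False):
        groups.append(OrthologGroup(
            group_id=f"og{row.component:06d}",
            members_a=frozenset(row.members_a.split(";")),
            members_b=frozenset(row.members_b.split(";")),
        ))
    return groups


def generate_expression(groups, config: SimConfig):
    """Expression records, a count matrix, and planted truth.

    Returns ``(expr, counts, truth)``:

    * ``expr`` — long table (gene, cell_type, rpkm, fdr) for every member
      gene of every group in every configured cell type; presence patterns
      over the Venn cell types are drawn from ``config.pattern_probs`` per
      component, the second fish paralog co-expresses with probability
      ``paralog_coexpression``, and zSC presence is independent;
    * ``counts`` — replicated NB counts for zHC vs zSC with
      ``n_de_genes`` planted at |log2 fold change| = ``de_log2fc``;
    * ``truth`` — dict with the per-group presence patterns, per-gene
      presence, and the planted DE gene table.
    """
    rng = config.rng("expression")
    cell_species = config.cell_species
    venn_types = sorted({ct for p in config.pattern_probs for ct in p})
    patterns = list(config.pattern_probs)
    probs = np.asarray([config.pattern_probs[p] for p in patterns], dtype=float)
    probs = probs / probs.sum()
    pattern_idx = rng.choice(len(patterns), size=len(groups), p=probs)

    expr_rows = []
    group_patterns = {}
    gene_presence = {}
    for g, pi in zip(groups, pattern_idx):
        pattern = set(patterns[pi])
        if "zSC" in cell_species and "zSC" not in venn_types:
            if rng.random() < config.zsc_presence:
                pattern.add("zSC")
        group_patterns[g.group_id] = frozenset(pattern)
        for ct, species in cell_species.items():
            members = sorted(g.members_a if species == "a" else g.members_b)
            present_ct = ct in pattern
            for j, gene in enumerate(members):
                if not present_ct:
                    present = False
                elif j == 0:
                    present = True
                else:
                    present = bool(rng.random() < config.paralog_coexpression)
                if present:
                    rpkm = 0.1 + float(rng.lognormal(config.rpkm_log_mean,
                                                     config.rpkm_log_sd))
                    fdr = float(rng.uniform(0.0, 0.10))
                else:
                    rpkm = float(rng.uniform(0.0, 0.099))
                    fdr = float(rng.uniform(0.11, 1.0))
                expr_rows.append({"gene": gene, "cell_type": ct,
                                  "rpkm": rpkm, "fdr": fdr})
                gene_presence[(gene, ct)] = present
    expr = pd.DataFrame(expr_rows, columns=["gene", "cell_type", "rpkm", "fdr"])

    counts, de_truth = _generate_counts(expr, config)
    truth = {
        "group_patterns": group_patterns,
        "gene_presence": gene_presence,
        "de_genes": de_truth,
    }
    return expr, counts, truth


def _generate_counts(expr: pd.DataFrame, config: SimConfig):
    """Replicated NB count matrix for zHC vs zSC with planted DE genes."""
    rng = config.rng("counts")
    wide = expr.pivot(index="gene", columns="cell_type", values="rpkm")
    if not {"zHC", "zSC"} <= set(wide.columns):
        return None, pd.DataFrame(columns=["gene", "log2fc"])
    base = wide["zHC"].fillna(0.0) * config.count_depth
    genes = base.index.to_numpy()
    mu_a = base.to_numpy(dtype=float)
    mu_b = mu_a.copy()
    # plant DE on well-expressed genes so the effect is identifiable
    eligible = np.flatnonzero(mu_a >= 20.0)
    n_de = min(config.n_de_genes, len(eligible))
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    mu_b[de_idx] = mu_a[de_idx] * 2.0 ** (-signs * config.de_log2fc)
    n_rep = config.n_replicates
    sf = rng.uniform(0.7, 1.3, 2 * n_rep)
    cols, data = [], []
    phi = config.nb_dispersion
    for r in range(2 * n_rep):
        mu = (mu_a if r < n_rep else mu_b) * sf[r]
        lam = rng.gamma(1.0 / phi, np.maximum(mu, 1e-12) * phi)
        data.append(rng.poisson(lam))
        cols.append(f"{'zHC' if r < n_rep else 'zSC'}_{r % n_rep + 1}")
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    de_truth = pd.DataFrame({
        "gene": genes[de_idx],
        "log2fc": signs * config.de_log2fc,   # zHC relative to zSC
    })
    return counts, de_truth


def staircase_protocol(v_start: float = -120.0, v_stop: float = 60.0,
                       step_mv: float = 4.0) -> np.ndarray:
    """Staircase command voltages in mV (inclusive of both ends)."""
    return np.arange(v_start, v_stop + 1e-9, step_mv)


def generate_recording(config: SimConfig, protocol=None, noise_sd: float | None = None,
                       include_motility: bool = True,
                       include_currents: bool = False,
                       rs_mohm: float = 10.0, rm_mohm: float = 500.0,
                       periods: int = 4) -> dict:
    """Synthetic voltage-clamp recording with known generating parameters.

    Capacitance is the NLC model at the staircase voltages plus Gaussian noise
    of SD ``noise_sd`` (pF; defaults to ``config.nlc_noise_sd``); displacement
    comes from the Boltzmann motility model.  With ``include_currents`` the
    raw dual-sine current trace of the 3-element patch circuit is simulated
    for each staircase step (``periods`` periods of the lower frequency).

    Returns a dict with ``recording`` (:class:`~orthoexpress.ephys.Recording`),
    ``truth`` (the generating parameters) and, when requested, ``currents``
    (list of per-step (voltage_trace, current_trace) arrays).
    """
    rng = config.rng("recording")
    v = staircase_protocol() if protocol is None else np.asarray(protocol, dtype=float)
    sd = config.nlc_noise_sd if noise_sd is None else noise_sd
    cap = nlc_curve(v, config.nlc_truth)
    if sd:
        cap = cap + rng.normal(0.0, sd, len(v))
    disp = None
    if include_motility:
        disp = boltzmann_length(v, config.motility_truth)
        if config.motility_noise_sd:
            disp = disp + rng.normal(0.0, config.motility_noise_sd, len(v))
    rec = Recording(
        voltage=v, capacitance=cap, displacement=disp,
        metadata={"f1_hz": F1_HZ, "f2_hz": F2_HZ,
                  "sample_rate_hz": SAMPLE_RATE_HZ, "noise_sd_pf": sd},
    )
    out = {"recording": rec,
           "truth": {"nlc": config.nlc_truth,
                     "motility": config.motility_truth if include_motility else None}}
    if include_currents:
        n = int(round(periods * SAMPLE_RATE_HZ / F1_HZ))
        traces = []
        for v_step in v:
            circuit = PatchCircuit(rs_mohm=rs_mohm, rm_mohm=rm_mohm,
                                   cm_pf=float(nlc_curve(v_step, config.nlc_truth)))
            traces.append(simulate_two_sine_current(circuit, n, v_dc_mv=float(v_step)))
        out["currents"] = traces
        out["truth"]["circuit"] = {"rs_mohm": rs_mohm, "rm_mohm": rm_mohm}
    return out
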