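"""Mass-action ODE model of competitive VEGF/semaphorin receptor binding.

One tumour interstitium contains two cell types, tumour cells and
endothelial cells (EC).  Both carry surface receptors (VEGFR1/2/3, the
neuropilins NRP1/2, and a lumped plexin-A species) and both secrete the
ligands — the five VEGF-family ligands (VEGFA split into its two major
isoforms VEGF165 and VEGF121) and the seven class-3 semaphorins — into the
shared interstitial fluid.  Ligands bind receptors reversibly; VEGF165
receptor complexes can couple with NRP1 into a ternary complex, and
Sema3-neuropilin complexes couple with plexin-A into the anti-angiogenic
ternary.  Because a neuropilin occupied by a Sema3 cannot join a VEGF
ternary (and vice versa), VEGFs and Sema3s compete for neuropilins.

Per-sample simulations scale the *tumour-cell* production rates by that
sample's expression relative to the normal-tissue mean, yielding one
steady-state receptor-occupancy profile per patient sample (a population of
models).  Key read-outs are the pro-angiogenic VEGFA.VEGFR2 "accelerator"
and the anti-angiogenic Sema3.NRP.PlxnA "brake" on each cell type.

Internal units: every species is held in pmol per litre of tissue; the
conversions from molar binding constants, per-cell surface densities and
the tissue geometry (interstitial fluid fraction, cell densities) are
centralised in :func:`compile_network`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import N_A
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .panel import ExpressionMatrix, TISSUE_NORMAL

EC = "EC"
TUM = "TUM"
CELLS = (EC, TUM)

SEMA3S = ("SEMA3A", "SEMA3B", "SEMA3C", "SEMA3D", "SEMA3E", "SEMA3F", "SEMA3G")
#: ligand species in interstitial fluid (VEGFA appears as its two isoforms)
LIGANDS = ("V165", "V121", "VEGFB", "VEGFC", "VEGFD", "PLGF") + SEMA3S
RECEPTORS = ("R1", "R2", "R3", "N1", "N2", "PLXNA")

#: which receptors each ligand binds directly
BINDING_RULES: dict[str, tuple[str, ...]] = {
    "V165": ("R1", "R2", "N1", "N2"),
    "V121": ("R1", "R2"),
    "PLGF": ("R1", "N1"),
    "VEGFB": ("R1", "N1"),
    "VEGFC": ("R2", "R3", "N2"),
    "VEGFD": ("R2", "R3", "N2"),
    **{s: ("N1", "N2") for s in SEMA3S},
}

#: secreted ligand pools addressed by gene-level production rates
PRODUCTION_LIGANDS = ("VEGFA", "VEGFB", "VEGFC", "VEGFD", "PLGF") + SEMA3S

#: couplings (binary complex + surface partner <-> ternary complex)
def _coupling_rules() -> list[tuple[str, str, str]]:
    rules = [("V165_R2", "N1", "V165_R2_N1"),
             ("V165_N1", "R2", "V165_R2_N1")]
    for s in SEMA3S:
        for n in ("N1", "N2"):
            rules.append((f"{s}_{n}", "PLXNA", f"{s}_{n}_PLXNA"))
    return rules

COUPLING_RULES = tuple(_coupling_rules())


@dataclass
class ParameterSet:
    """Kinetic, transport and geometric parameters of the binding network.

    kon/koff:     per ligand-receptor pair, M^-1 s^-1 and s^-1.
    kc_on/kc_off: per coupling (keyed "<binary>+<partner>"),
                  (molecules/cell)^-1 s^-1 and s^-1.
    secretion:    molecules per cell per second, keyed (cell, ligand gene);
                  VEGFA is split between VEGF165/VEGF121 by
                  ``vegfa_iso_fraction_165``.
    insertion:    receptor delivery to the surface, molecules/cell/s.
    k_int:        first-order internalisation of every surface species, s^-1.
    k_deg:        first-order degradation of free interstitial ligand, s^-1.
    fluid_fraction: interstitial fluid volume fraction of the tissue.
    cell_density: cells per litre of tissue per cell type.
    """

    kon: dict[tuple[str, str], float]
    koff: dict[tuple[str, str], float]
    kc_on: dict[str, float]
    kc_off: dict[str, float]
    secretion: dict[tuple[str, str], float]
    insertion: dict[tuple[str, str], float]
    k_int: dict[str, float]
    k_deg: float
    fluid_fraction: float
    cell_density: dict[str, float]
    vegfa_iso_fraction_165: float = 0.5
    scaling_clamp: tuple[float, float] = (0.01, 100.0)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def kd(self, ligand: str, receptor: str) -> float:
        return self.koff[(ligand, receptor)] / self.kon[(ligand, receptor)]


def default_parameters() -> ParameterSet:
    """Literature-nominal kinetics and geometry for the default network.

    Affinities follow the usual VEGF-model values (VEGFR1 tighter than
    VEGFR2; neuropilin binding of VEGF165 in the hundreds of pM; Sema3-NRP
    in the low-nM range), surface densities put neuropilins in excess of
    occupied complexes, and the coupling constant for the second route into
    the VEGF165.VEGFR2.NRP1 ternary is derived from thermodynamic cycle
    closure rather than chosen independently.
    """
    kon = {
        ("V165", "R1"): 3e7, ("V165", "R2"): 1e7,
        ("V165", "N1"): 3.2e6, ("V165", "N2"): 3.2e6,
        ("V121", "R1"): 3e7, ("V121", "R2"): 1e7,
        ("PLGF", "R1"): 1e7, ("PLGF", "N1"): 3.2e6,
        ("VEGFB", "R1"): 1e7, ("VEGFB", "N1"): 3.2e6,
        ("VEGFC", "R2"): 1e7, ("VEGFC", "R3"): 1e7, ("VEGFC", "N2"): 3.2e6,
        ("VEGFD", "R2"): 1e7, ("VEGFD", "R3"): 1e7, ("VEGFD", "N2"): 3.2e6,
    }
    koff = {
        ("V165", "R1"): 1e-3, ("V165", "R2"): 1e-3,
        ("V165", "N1"): 1e-3, ("V165", "N2"): 1e-3,
        ("V121", "R1"): 1e-3, ("V121", "R2"): 1e-3,
        ("PLGF", "R1"): 2e-3, ("PLGF", "N1"): 1e-3,
        ("VEGFB", "R1"): 2e-3, ("VEGFB", "N1"): 1e-3,
        ("VEGFC", "R2"): 1e-2, ("VEGFC", "R3"): 1e-3, ("VEGFC", "N2"): 1e-3,
        ("VEGFD", "R2"): 1e-2, ("VEGFD", "R3"): 1e-3, ("VEGFD", "N2"): 1e-3,
    }
    for s in SEMA3S:
        for n in ("N1", "N2"):
            kon[(s, n)] = 2e5      # Kd = 10 nM: weak enough that neuropilins
            koff[(s, n)] = 2e-3    # stay in excess of occupied complexes

    kc_on = {"V165_R2+N1": 1e-4, "V165_N1+R2": 1e-4}
    kc_off = {"V165_R2+N1": 1e-2}
    # cycle closure: Kd(V.R2) Kc(V.R2+N1) = Kd(V.N1) Kc(V.N1+R2)
    kc_off["V165_N1+R2"] = (
        kc_off["V165_R2+N1"] * kc_on["V165_N1+R2"] / kc_on["V165_R2+N1"]
        * (koff[("V165", "R2")] * kon[("V165", "N1")])
        / (koff[("V165", "N1")] * kon[("V165", "R2")])
    )
    for s in SEMA3S:
        for n in ("N1", "N2"):
            kc_on[f"{s}_{n}+PLXNA"] = 2e-5
            kc_off[f"{s}_{n}+PLXNA"] = 2e-2

    k_int = {EC: 2.8e-4, TUM: 2.8e-4}   # ~ 1 h receptor residence
    # insertion rates chosen to give steady free-receptor levels (molec/cell)
    # EC: R1 1e4, R2 1e4, R3 2e3, N1 2.5e4, N2 1e4, PLXNA 5e3
    # TUM: R1 1e3, R2 1e3, R3 5e2, N1 3e3, N2 3e3, PLXNA 5e3
    level = {
        (EC, "R1"): 1e4, (EC, "R2"): 1e4, (EC, "R3"): 2e3,
        (EC, "N1"): 2.5e4, (EC, "N2"): 1e4, (EC, "PLXNA"): 5e3,
        (TUM, "R1"): 1e3, (TUM, "R2"): 1e3, (TUM, "R3"): 5e2,
        (TUM, "N1"): 1e3, (TUM, "N2"): 1e3, (TUM, "PLXNA"): 2e3,
    }
    insertion = {k: v * k_int[k[0]] for k, v in level.items()}

    secretion = {}
    q = {"VEGFA": 0.02, "VEGFB": 0.01, "VEGFC": 0.005, "VEGFD": 0.005,
         "PLGF": 0.005, **{s: 0.01 for s in SEMA3S}}
    for cell in CELLS:
        for lig, rate in q.items():
            secretion[(cell, lig)] = rate

    return ParameterSet(
        kon=kon, koff=koff, kc_on=kc_on, kc_off=kc_off,
        secretion=secretion, insertion=insertion,
        k_int=k_int, k_deg=5e-4,
        fluid_fraction=0.3,
        cell_density={EC: 5e9, TUM: 2e11},
    )


@dataclass
class BindingNetwork:
    """Enumerated species and reactions (symbolic, before rate compilation)."""

    species: list[str]
    composition: dict[str, dict[str, int]]      # species -> monomer counts
    reactions: list[dict]

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}


def _surface(cell: str, name: str) -> str:
    return f"{cell}:{name}"


def enumerate_network() -> BindingNetwork:
    """Closure of the binding and coupling rules over both cell types."""
    species: list[str] = list(LIGANDS)
    composition = {lig: {lig: 1} for lig in LIGANDS}
    reactions: list[dict] = []

    def add_species(name: str, comp: dict[str, int]) -> None:
        if name not in composition:
            species.append(name)
            composition[name] = comp

    for cell in CELLS:
        for rec in RECEPTORS:
            add_species(_surface(cell, rec), {f"{cell}:{rec}": 1})
        for lig, recs in BINDING_RULES.items():
            for rec in recs:
                cpx = _surface(cell, f"{lig}_{rec}")
                add_species(cpx, {lig: 1, f"{cell}:{rec}": 1})
                reactions.append({"kind": "binding", "cell": cell,
                                  "ligand": lig, "receptor": rec,
                                  "reactants": (lig, _surface(cell, rec)),
                                  "product": cpx})
        for binary, partner, ternary in COUPLING_RULES:
            b = _surface(cell, binary)
            t = _surface(cell, ternary)
            comp = dict(composition[b])
            key = f"{cell}:{partner}"
            comp[key] = comp.get(key, 0) + 1
            add_species(t, comp)
            reactions.append({"kind": "coupling", "cell": cell,
                              "key": f"{binary}+{partner}",
                              "reactants": (b, _surface(cell, partner)),
                              "product": t})
    return BindingNetwork(species=species, composition=composition,
                          reactions=reactions)


def default_network() -> tuple[BindingNetwork, ParameterSet]:
    """The default reaction network and its nominal parameters."""
    return enumerate_network(), default_parameters()


class CompiledNetwork:
    """Stoichiometry + rate constants in consistent tissue units (pmol/L).

    Reactions are elementary: zeroth order (secretion/insertion), first
    order (dissociation, internalisation, degradation) or second order
    (binding, coupling).  The right-hand side is ``S @ rates(x)`` and the
    Jacobian is assembled analytically from the same structure.
    """

    def __init__(self, params: ParameterSet,
                 network: BindingNetwork | None = None,
                 closed_system: bool = False):
        self.params = params
        self.network = network or enumerate_network()
        self.closed_system = closed_system
        self._verify_cycle_closure()
        self._compile()

    # thermodynamic consistency of the VEGF165/VEGFR2/NRP1 cycle
    def _verify_cycle_closure(self, rtol: float = 1e-10) -> None:
        p = self.params
        lhs = p.kd("V165", "R2") * (p.kc_off["V165_R2+N1"] / p.kc_on["V165_R2+N1"])
        rhs = p.kd("V165", "N1") * (p.kc_off["V165_N1+R2"] / p.kc_on["V165_N1+R2"])
        if abs(lhs - rhs) > rtol * max(abs(lhs), abs(rhs)):
            raise ValueError(
                "detailed-balance violation in the VEGF165/VEGFR2/NRP1 cycle: "
                f"{lhs:.6e} != {rhs:.6e}")

    def _compile(self) -> None:
        p = self.params
        net = self.network
        idx = net.index
        ns = len(net.species)
        phi = p.fluid_fraction

        r1, r2, ks = [], [], []
        stoich: list[dict[int, float]] = []

        def add(kconst: float, reactants: tuple[int, ...], products: tuple[int, ...]) -> None:
            col: dict[int, float] = {}
            for s in reactants:
                col[s] = col.get(s, 0.0) - 1.0
            for s in products:
                col[s] = col.get(s, 0.0) + 1.0
            a = reactants[0] if len(reactants) >= 1 else -1
            b = reactants[1] if len(reactants) >= 2 else -1
            r1.append(a)
            r2.append(b)
            ks.append(kconst)
            stoich.append(col)

        surf_conv = {c: p.cell_density[c] / N_A * 1e12 for c in CELLS}  # molec/cell -> pM tissue

        for rx in net.reactions:
            cell = rx["cell"]
            a, b = (idx[s] for s in rx["reactants"])
            c = idx[rx["product"]]
            if rx["kind"] == "binding":
                kon_eff = p.kon[(rx["ligand"], rx["receptor"])] * 1e-12 / phi
                koff = p.koff[(rx["ligand"], rx["receptor"])]
            else:
                kon_eff = p.kc_on[rx["key"]] * N_A / (p.cell_density[cell] * 1e12)
                koff = p.kc_off[rx["key"]]
            add(kon_eff, (a, b), (c,))
            add(koff, (c,), (a, b))

        if not self.closed_system:
            for (cell, lig), q in p.secretion.items():
                rate = q * surf_conv[cell]
                if lig == "VEGFA":
                    f = p.vegfa_iso_fraction_165
                    add(rate * f, (), (idx["V165"],))
                    add(rate * (1 - f), (), (idx["V121"],))
                else:
                    target = _gene_to_ligand(lig)
                    add(rate, (), (idx[target],))
            for (cell, rec), s in p.insertion.items():
                add(s * surf_conv[cell], (), (idx[_surface(cell, rec)],))
            for name in net.species:
                if ":" in name:   # surface species internalise
                    add(p.k_int[name.split(":", 1)[0]], (idx[name],), ())
                else:             # free ligand degrades
                    add(p.k_deg, (idx[name],), ())

        nr = len(ks)
        self.n_species = ns
        self.k = np.array(ks)
        self.r1 = np.array(r1, dtype=int)
        self.r2 = np.array(r2, dtype=int)
        self.S = np.zeros((ns, nr))
        for j, col in enumerate(stoich):
            for s, v in col.items():
                self.S[s, j] = v
        self._has1 = self.r1 >= 0
        self._has2 = self.r2 >= 0
        # composition matrix for conservation checks (monomers x species)
        monomers = sorted({m for comp in net.composition.values() for m in comp})
        self.monomers = monomers
        self.C = np.zeros((len(monomers), ns))
        for s, comp in net.composition.items():
            for mname, cnt in comp.items():
                self.C[monomers.index(mname), idx[s]] = cnt

    # -- dynamics --------------------------------------------------------
    def rates(self, x: np.ndarray) -> np.ndarray:
        v = self.k.copy()
        v[self._has1] *= x[self.r1[self._has1]]
        v[self._has2] *= x[self.r2[self._has2]]
        return v

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(x)

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        nr = len(self.k)
        D = np.zeros((nr, self.n_species))
        j_idx = np.arange(nr)
        d1 = self.k.copy()
        d1[self._has2] *= x[self.r2[self._has2]]
        np.add.at(D, (j_idx[self._has1], self.r1[self._has1]), d1[self._has1])
        d2 = self.k.copy()
        d2[self._has1] *= x[self.r1[self._has1]]
        np.add.at(D, (j_idx[self._has2], self.r2[self._has2]), d2[self._has2])
        return self.S @ D

    def ligand_free_steady_state(self) -> np.ndarray:
        """Closed-form initial state: free receptors at insertion/internalisation."""
        p = self.params
        x0 = np.zeros(self.n_species)
        idx = self.network.index
        conv = {c: p.cell_density[c] / N_A * 1e12 for c in CELLS}
        if not self.closed_system:
            for (cell, rec), s in p.insertion.items():
                x0[idx[_surface(cell, rec)]] = s * conv[cell] / p.k_int[cell]
        return x0

    def monomer_totals(self, x: np.ndarray) -> np.ndarray:
        return self.C @ x


def _gene_to_ligand(gene: str) -> str:
    if gene == "VEGFA":
        raise ValueError("VEGFA is split by isoform, handled separately")
    return gene  # VEGFB/VEGFC/VEGFD/PLGF/SEMA3x match species names


#: gene symbols -> (rate table, network key) for production scaling
GENE_RATE_TARGETS = {
    "VEGFA": ("secretion", "VEGFA"), "VEGFB": ("secretion", "VEGFB"),
    "VEGFC": ("secretion", "VEGFC"), "FIGF": ("secretion", "VEGFD"),
    "PGF": ("secretion", "PLGF"),
    **{s: ("secretion", s) for s in SEMA3S},
    "FLT1": ("insertion", "R1"), "KDR": ("insertion", "R2"),
    "FLT4": ("insertion", "R3"), "NRP1": ("insertion", "N1"),
    "NRP2": ("insertion", "N2"),
}
PLXNA_GENES = ("PLXNA1", "PLXNA2", "PLXNA3", "PLXNA4")


def expression_scale_factors(
    m: ExpressionMatrix, sample_id: str, reference: str = TISSUE_NORMAL,
) -> dict[str, float]:
    """Linear-scale production factors: 2^x over the normal-group mean of 2^x.

    Returns one factor per mapped gene plus a ``PLXNA`` factor computed from
    the summed linear expression of PLXNA1-4 (the lumped plexin species).
    """
    ref = m.group_values(reference)
    if ref.shape[0] == 0:
        raise ValueError(f"no {reference!r} reference samples")
    if sample_id not in m.values.index:
        raise ValueError(f"unknown sample {sample_id!r}")
    row = m.values.loc[sample_id]
    factors: dict[str, float] = {}
    for gene in GENE_RATE_TARGETS:
        if gene not in m.values.columns:
            raise ValueError(f"gene {gene!r} absent from expression matrix")
        factors[gene] = float(2.0 ** row[gene] / np.mean(2.0 ** ref[gene]))
    for g in PLXNA_GENES:
        if g not in m.values.columns:
            raise ValueError(f"gene {g!r} absent from expression matrix")
    lin = sum(2.0 ** row[g] for g in PLXNA_GENES)
    lin_ref = float(np.mean(np.sum(2.0 ** ref[list(PLXNA_GENES)], axis=1)))
    factors["PLXNA"] = float(lin / lin_ref)
    return factors


def scale_production(
    nominal: ParameterSet, m: ExpressionMatrix, sample_id: str,
    reference: str = TISSUE_NORMAL,
) -> ParameterSet:
    """Tumour-cell production rates scaled by one sample's expression.

    Only tumour-cell secretion/insertion is varied; endothelial rates stay
    nominal.  Factors are clamped to ``nominal.scaling_clamp``.
    """
    factors = expression_scale_factors(m, sample_id, reference)
    lo, hi = nominal.scaling_clamp
    p = nominal.copy()
    for gene, (table, key) in GENE_RATE_TARGETS.items():
        f = min(max(factors[gene], lo), hi)
        if table == "secretion":
            p.secretion[(TUM, key)] = nominal.secretion[(TUM, key)] * f
        else:
            p.insertion[(TUM, key)] = nominal.insertion[(TUM, key)] * f
    f = min(max(factors["PLXNA"], lo), hi)
    p.insertion[(TUM, "PLXNA")] = nominal.insertion[(TUM, "PLXNA")] * f
    return p


# -- steady-state solution ----------------------------------------------
AGGREGATES = ("vegfa_vegfr2", "vegfa_vegfr1", "sema3_nrp_plxna")


def aggregate_indices(net: BindingNetwork) -> dict[tuple[str, str], list[int]]:
    idx = net.index
    out: dict[tuple[str, str], list[int]] = {}
    for cell in CELLS:
        out[(cell, "vegfa_vegfr2")] = [
            idx[_surface(cell, "V165_R2")], idx[_surface(cell, "V121_R2")],
            idx[_surface(cell, "V165_R2_N1")]]
        out[(cell, "vegfa_vegfr1")] = [
            idx[_surface(cell, "V165_R1")], idx[_surface(cell, "V121_R1")]]
        out[(cell, "sema3_nrp_plxna")] = [
            idx[_surface(cell, f"{s}_{n}_PLXNA")]
            for s in SEMA3S for n in ("N1", "N2")]
    return out


@dataclass
class SampleSimulationResult:
    """Steady state of one sample's network plus derived aggregates."""

    sample_id: str
    species: pd.Series
    aggregates: dict[tuple[str, str], float]
    converged: bool
    t_final: float
    max_rel_rate_per_hour: float
    error: str | None = None


def simulate_to_steady_state(
    compiled: CompiledNetwork,
    sample_id: str = "sample",
    x0: np.ndarray | None = None,
    rel_rate_tol: float = 1e-6,
    rtol: float = 1e-8,
    t_max: float = 1e9,
    cross_check: bool = False,
    cross_check_rtol: float = 1e-3,
) -> SampleSimulationResult:
    """Integrate the stiff ODE system until the state stops moving.

    Starts from the ligand-free receptor steady state and integrates in
    doubling time spans until the largest relative rate of change drops
    below ``rel_rate_tol`` per simulated hour.  With ``cross_check`` the
    result is verified against an independent algebraic root solve.
    """
    x = compiled.ligand_free_steady_state() if x0 is None else x0.copy()
    scale = max(x.max(), 1.0)
    atol = 1e-12 * scale
    floor = 1e-9 * scale

    def rel_rate(xv: np.ndarray) -> float:
        f = compiled.rhs(0.0, xv)
        return float(np.max(np.abs(f) * 3600.0 / (np.abs(xv) + floor)))

    t_end = 1e4
    t_total = 0.0
    converged = False
    while t_total < t_max:
        sol = solve_ivp(compiled.rhs, (0.0, t_end), x, method="BDF",
                        jac=compiled.jac, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed for {sample_id}: {sol.message}")
        x = sol.y[:, -1]
        t_total += t_end
        if x.min() < -1e-12 * max(x.max(), 1.0):
            raise RuntimeError(
                f"negative species abundance for {sample_id}: min={x.min():.3e}")
        x = np.maximum(x, 0.0)
        if rel_rate(x) < rel_rate_tol:
            converged = True
            break
        t_end *= 2
    if not converged:
        raise RuntimeError(
            f"no steady state for {sample_id} within {t_max:.0e} s "
            f"(residual relative rate {rel_rate(x):.2e}/h)")

    if cross_check:
        alg = steady_state_root(compiled, x)
        big = np.abs(x) > 1e-6 * scale
        rel = np.abs(alg - x)[big] / np.abs(x)[big]
        if rel.max() > cross_check_rtol:
            raise RuntimeError(
                f"ODE and algebraic steady states disagree: max rel {rel.max():.2e}")

    agg_idx = aggregate_indices(compiled.network)
    aggregates = {key: float(x[idxs].sum()) for key, idxs in agg_idx.items()}
    return SampleSimulationResult(
        sample_id=sample_id,
        species=pd.Series(x, index=compiled.network.species),
        aggregates=aggregates, converged=True, t_final=t_total,
        max_rel_rate_per_hour=rel_rate(x))


def steady_state_root(compiled: CompiledNetwork, x0: np.ndarray) -> np.ndarray:
    """Independent algebraic steady state: solve rhs(x) = 0 near x0.

    Solved in log abundance (x = x0 * exp(u)), which both enforces
    positivity and equalises the scales of species spanning many orders of
    magnitude.
    """
    base = np.maximum(x0, 1e-30)

    def fun(u: np.ndarray) -> np.ndarray:
        return compiled.rhs(0.0, base * np.exp(u))

    def jac(u: np.ndarray) -> np.ndarray:
        x = base * np.exp(u)
        return compiled.jac(0.0, x) * x[None, :]

    # start away from x0 so the solver finds the root on its own
    u0 = np.full(len(base), 0.5)
    sol = root(fun, u0, jac=jac, method="hybr", options={"xtol": 1e-13})
    x = base * np.exp(sol.x)
    residual_scale = max(np.abs(compiled.rates(x)).max(), 1e-30)
    if not sol.success and np.abs(fun(sol.x)).max() > 1e-8 * residual_scale:
        raise RuntimeError(f"algebraic steady-state solve failed: {sol.message}")
    return x


def run_population(
    nominal: ParameterSet,
    m: ExpressionMatrix,
    sample_ids: list[str] | None = None,
    reference: str = TISSUE_NORMAL,
    network: BindingNetwork | None = None,
    **solve_kwargs,
) -> list[SampleSimulationResult]:
    """One steady-state simulation per sample with its scaled parameters.

    Per-sample failures are recorded in the result (``converged=False``)
    without aborting the batch; an all-failed batch raises.
    """
    network = network or enumerate_network()
    ids = list(sample_ids) if sample_ids is not None else list(m.sample_ids)
    results: list[SampleSimulationResult] = []
    n_ok = 0
    for sid in ids:
        try:
            params = scale_production(nominal, m, sid, reference)
            compiled = CompiledNetwork(params, network=network)
            res = simulate_to_steady_state(compiled, sample_id=sid, **solve_kwargs)
            n_ok += 1
        except RuntimeError as exc:
            res = SampleSimulationResult(
                sample_id=sid, species=pd.Series(dtype=float), aggregates={},
                converged=False, t_final=np.nan,
                max_rel_rate_per_hour=np.nan, error=str(exc))
        results.append(res)
    if n_ok == 0:
        raise RuntimeError("every sample simulation failed")
    return results


def aggregates_frame(results: list[SampleSimulationResult],
                     m: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Tidy per-sample table of aggregates (tissue pmol/L), plus tissue type."""
    rows = {}
    for r in results:
        if not r.converged:
            continue
        rows[r.sample_id] = {f"{cell}:{name}": v
                             for (cell, name), v in r.aggregates.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if m is not None:
        df["tissue_type"] = m.metadata.loc[df.index, "tissue_type"]
    return df


def p_value_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare_complexes(
    results: list[SampleSimulationResult], m: ExpressionMatrix,
    cell: str = EC,
) -> pd.DataFrame:
    """Welch t-tests on log-transformed aggregates between tissue groups."""
    from .diffexp import welch_t_two_tailed
    df = aggregates_frame(results, m)
    groups = [g for g in df["tissue_type"].unique()]
    rows = []
    for name in AGGREGATES:
        col = f"{cell}:{name}"
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = np.log10(df.loc[df["tissue_type"] == ga, col].to_numpy())
                b = np.log10(df.loc[df["tissue_type"] == gb, col].to_numpy())
                if len(a) < 2 or len(b) < 2:
                    continue
                t, dfree, p = welch_t_two_tailed(b, a)
                rows.append({"aggregate": name, "cell": cell, "group_a": ga,
                             "group_b": gb, "t_stat": t, "p": p,
                             "stars": p_value_stars(p)})
    return pd.DataFrame(rows)


def _sema3_log2_sum(m: ExpressionMatrix) -> pd.Series:
    lin = sum(2.0 ** m.values[s] for s in SEMA3S)
    return np.log2(lin)


def variance_explained(
    results: list[SampleSimulationResult], m: ExpressionMatrix,
    cell: str = EC,
) -> pd.DataFrame:
    """Least-squares fits of log10 receptor binding on ligand expression.

    Direct pairs: VEGFA expression vs the VEGFR1/VEGFR2 aggregates; total
    Sema3 expression (log2 of summed linear expression) vs the ternary.
    Cross pairs quantify the competitive leak between the two axes.
    """
    df = aggregates_frame(results, m)
    if df.shape[0] < 3:
        raise ValueError("need >= 3 converged samples")
    predictors = {
        "VEGFA": m.values.loc[df.index, "VEGFA"].to_numpy(),
        "SEMA3_total": _sema3_log2_sum(m).loc[df.index].to_numpy(),
    }
    responses = {
        "vegfa_vegfr2": np.log10(df[f"{cell}:vegfa_vegfr2"].to_numpy()),
        "vegfa_vegfr1": np.log10(df[f"{cell}:vegfa_vegfr1"].to_numpy()),
        "sema3_nrp_plxna": np.log10(df[f"{cell}:sema3_nrp_plxna"].to_numpy()),
    }
    pairs = [
        ("VEGFA", "vegfa_vegfr2", "direct"), ("VEGFA", "vegfa_vegfr1", "direct"),
        ("SEMA3_total", "sema3_nrp_plxna", "direct"),
        ("VEGFA", "sema3_nrp_plxna", "cross"),
        ("SEMA3_total", "vegfa_vegfr2", "cross"),
        ("SEMA3_total", "vegfa_vegfr1", "cross"),
    ]
    rows = []
    for pred, resp, kind in pairs:
        xv = predictors[pred]
        if np.var(xv) == 0:
            raise ValueError(f"zero-variance predictor {pred}")
        fit = stats.linregress(xv, responses[resp])
        rows.append({"predictor": pred, "response": resp, "kind": kind,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "r2": fit.rvalue ** 2})
    return pd.DataFrame(rows)


def quadrant_classify(
    results: list[SampleSimulationResult], m: ExpressionMatrix,
    cell: str = EC, benign_tissue: str = TISSUE_NORMAL,
) -> pd.DataFrame:
    """Accelerator/brake quadrants relative to benign-group medians.

    Accelerator ON iff VEGFA.VEGFR2 strictly exceeds the benign median;
    brake OFF iff the Sema3 ternary is strictly below the benign median
    (samples exactly at a median take the non-extreme side).
    """
    df = aggregates_frame(results, m)
    benign = df[df["tissue_type"] == benign_tissue]
    if benign.empty:
        raise ValueError(f"no {benign_tissue!r} samples among converged results")
    acc_thr = float(benign[f"{cell}:vegfa_vegfr2"].median())
    brake_thr = float(benign[f"{cell}:sema3_nrp_plxna"].median())
    out = pd.DataFrame(index=df.index)
    out["tissue_type"] = df["tissue_type"]
    out["accelerator_on"] = df[f"{cell}:vegfa_vegfr2"] > acc_thr
    out["brake_off"] = df[f"{cell}:sema3_nrp_plxna"] < brake_thr
    out["quadrant"] = (
        np.where(out["accelerator_on"], "accel_ON", "accel_OFF") + "/" +
        np.where(out["brake_off"], "brake_OFF", "brake_ON"))
    out.attrs["thresholds"] = {"accelerator": acc_thr, "brake": brake_thr}
    return out
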