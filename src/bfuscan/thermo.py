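"""Redox couples of the Bfu third reactions and bifurcation energetics.

The packaged table holds the standard (pH 7) potential E°′ of each class's
third reaction, alongside the NAD(H), NADP(H) and ferredoxin carrier
couples with their physiological effective potentials E′.  Third reactions
fall into three potential groups anchored at the two carrier couples:
high (E°′ > −320 mV), mid (−420..−320 mV) and low (E°′ < −420 mV) — the mid
group is the set that fits energetically between NAD(H) and Fd.

Free-energy bookkeeping uses ΔG = −n·F·ΔE per two-electron leg with
F = 96.485 kJ·mol⁻¹·V⁻¹; ferredoxin is treated as a two-electron carrier.
"""

from __future__ import annotations

from dataclasses import dataclass

FARADAY_KJ_PER_MOL_V = 96.485

#: Category bounds are the NAD and Fd standard couples (mV).
HIGH_BOUND_MV = -320.0
LOW_BOUND_MV = -420.0


@dataclass(frozen=True)
class RedoxCouple:
    name: str
    half_reaction: str
    e0_prime_mv: float  # standard potential at pH 7, mV
    e_phys_mv: float | None = None  # physiological effective potential, mV
    n_electrons: int = 2
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.n_electrons not in (1, 2):
            raise ValueError("n_electrons must be 1 or 2")

    @property
    def effective_mv(self) -> float:
        """Physiological potential when known, standard otherwise."""
        return self.e_phys_mv if self.e_phys_mv is not None else self.e0_prime_mv


def _c(name, rxn, e0, phys=None, prov=""):
    return RedoxCouple(name, rxn, e0, phys, 2, prov)


#: Electron-carrier couples addressed by name.
CARRIER_COUPLES: dict[str, RedoxCouple] = {
    "NAD": _c("NAD", "NAD+ + 2e- + H+ = NADH", -320, -280, "carrier couple"),
    "NADP": _c("NADP", "NADP+ + 2e- + H+ = NADPH", -320, -380, "carrier couple"),
    "Fd": _c("Fd", "Fd_ox + 2e- = Fd_red", -420, -500,
             "carrier couple; Fd as two-electron carrier"),
}

#: Third-reaction couples of the twelve packaged classes/configurations.
THIRD_REACTION_COUPLES: dict[str, RedoxCouple] = {
    "Rub": _c("Rub", "H2O2 + 2H+ + 2e- = 2 H2O", +1349,
              prov="hydrogen peroxide/water couple"),
    "Nuo": _c("Nuo", "MQ + 2H+ + 2e- = MQH2", -74, prov="menaquinone couple"),
    "Nfn": _c("Nfn", "NADP+ + H+ + 2e- = NADPH", -320, -380,
              prov="NADP third reaction"),
    "F420": _c("F420", "F420 + H+ + 2e- = F420H2", -360, prov="cofactor F420"),
    "NiFe": _c("NiFe", "2H+ + 2e- = H2", -414, prov="hydrogen couple"),
    "Mbh": _c("Mbh", "2H+ + 2e- = H2", -414, prov="hydrogen couple"),
    "FeFe": _c("FeFe", "2H+ + 2e- = H2", -414, prov="hydrogen couple"),
    "Fdh": _c("Fdh", "CO2 + H+ + 2e- = HCOO-", -420, prov="formate couple"),
    "Por": _c("Por", "CO2 + acetyl-CoA + 2e- = pyruvate + CoA", -500,
              prov="pyruvate synthase couple"),
    "Codh": _c("Codh", "CO2 + 2H+ + 2e- = CO + H2O", -520,
               prov="carbon monoxide couple"),
    "Wor": _c("Wor", "RCOO- + 3H+ + 2e- = RCHO + H2O", -560,
              prov="aldehyde couple"),
    "Bam": _c("Bam", "dienoyl-CoA + 2e- + H2O = benzoyl-CoA", -620,
              prov="aryl-CoA thioester couple (table value)"),
}

#: The in-text benzoyl-CoA value differs from the tabulated Bam row by 2 mV;
#: both are packaged, the discrepancy preserved rather than resolved.
NAMED_COUPLES: dict[str, RedoxCouple] = {
    **CARRIER_COUPLES,
    "BenzoylCoA": _c("BenzoylCoA", "dienoyl-CoA + 2e- + H2O = benzoyl-CoA",
                     -622, prov="benzoyl-CoA couple (text value)"),
}

#: Functional classes with no dedicated row map onto their operative couple.
_CLASS_ALIASES = {"FdhFeFe": "Fdh"}


def lookup_couple(class_name: str) -> RedoxCouple:
    """Third-reaction couple of a functional class; carriers by name."""
    key = _CLASS_ALIASES.get(class_name, class_name)
    if key in THIRD_REACTION_COUPLES:
        return THIRD_REACTION_COUPLES[key]
    if key in NAMED_COUPLES:
        return NAMED_COUPLES[key]
    raise KeyError(f"no redox couple for class {class_name!r}")


def categorize(couple: RedoxCouple) -> str:
    """Potential category: high (> −320), mid (−420..−320) or low (< −420)."""
    e = couple.e0_prime_mv
    if e > HIGH_BOUND_MV:
        return "high"
    if e >= LOW_BOUND_MV:
        return "mid"
    return "low"


def span_volts(couples: list[RedoxCouple]) -> float:
    """Spread of standard potentials across ``couples``, in volts."""
    if len(couples) < 2:
        raise ValueError("need at least 2 couples")
    values = [c.e0_prime_mv for c in couples]
    return (max(values) - min(values)) / 1000.0


@dataclass(frozen=True)
class EnergeticsResult:
    class_name: str
    donor_mv: float
    legs: tuple[tuple[str, float, float], ...]  # (acceptor, ΔE mV, ΔG kJ/mol)
    net_kj_per_mol: float
    electrons_per_leg: int = 2


def leg_delta_g(
    donor_mv: float, acceptor_mv: float, n_electrons: int = 2
) -> float:
    """ΔG = −n·F·(E_acceptor − E_donor), potentials in mV, ΔG in kJ/mol."""
    return -n_electrons * FARADAY_KJ_PER_MOL_V * (acceptor_mv - donor_mv) / 1000.0


def bifurcation_energetics(
    class_name: str, use_physiological: bool = True
) -> EnergeticsResult:
    """Per-leg and net ΔG of the bifurcating direction for one class.

    The third substrate donates two electron pairs: one two-electron leg to
    NAD(H) (exergonic for mid-potential donors) and one to Fd (endergonic);
    the net is their sum, conserved exactly.
    """
    third = lookup_couple(class_name)
    donor = third.effective_mv if use_physiological else third.e0_prime_mv
    legs = []
    net = 0.0
    for acceptor_name in ("NAD", "Fd"):
        acc = CARRIER_COUPLES[acceptor_name]
        e_acc = acc.effective_mv if use_physiological else acc.e0_prime_mv
        dg = leg_delta_g(donor, e_acc)
        legs.append((acceptor_name, e_acc - donor, dg))
        net += dg
    return EnergeticsResult(class_name, donor, tuple(legs), net)


def specific_activity(
    slope_abs_per_min: float,
    epsilon_mM_cm: float,
    pathlength_cm: float = 1.0,
    volume_mL: float = 1.0,
    protein_mg: float = 1.0,
    stoich_e_per_acceptor: int = 1,
) -> float:
    """Convert an absorbance slope into specific activity (U/mg).

    Beer-Lambert: slope / (ε·path) gives the acceptor concentration change
    in mM/min (= µmol/mL/min); scaling by the assay volume and dividing by
    protein yields µmol acceptor per minute per mg — one U/mg per µmol/min.
    ``stoich_e_per_acceptor`` divides out multi-electron acceptors when the
    unit is defined per electron pair rather than per acceptor molecule.
    """
    if min(epsilon_mM_cm, pathlength_cm, protein_mg, volume_mL) <= 0:
        raise ValueError("epsilon, pathlength, volume and protein must be positive")
    if stoich_e_per_acceptor < 1:
        raise ValueError("stoichiometry must be >= 1")
    rate_mM_per_min = slope_abs_per_min / (epsilon_mM_cm * pathlength_cm)
    umol_per_min = rate_mM_per_min * volume_mL / stoich_e_per_acceptor
    return umol_per_min / protein_mg


def couple_table() -> list[dict]:
    """JSON-ready dump of the packaged couples with categories."""
    out = []
    for name, c in {**THIRD_REACTION_COUPLES, **NAMED_COUPLES}.items():
        out.append(
            {
                "name": name,
                "half_reaction": c.half_reaction,
                "e0_prime_mv": c.e0_prime_mv,
                "e_phys_mv": c.e_phys_mv,
                "n_electrons": c.n_electrons,
                "category": categorize(c),
                "provenance": c.provenance,
            }
        )
    return out
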