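"""Synthetic fixtures with known ground truth for every analysis stage.

Every generator is fully deterministic under a fixed seed, and seeds are
derived per generator (stable hash of the generator name mixed with the user
seed) so adding a new generator never perturbs existing fixtures.  When an
output path is given, each generator writes the same TSV/CSV dialect the
analysis stages read plus a ``<name>.truth.json`` sidecar holding the ground
truth, which recovery tests consume.

The defaults encode the study conditions the analyses are meant to
reproduce: strain-wise serine incorporation levels, uptake-rate ratios and
labeled-lipid fractions mirror the wild-type/transporter-mutant contrasts of
the serine-uptake experiments (e.g. a gnp1 deletion retaining 35% of
wild-type uptake), and the toy metabolic network encodes the core serine
economy (synthesis via the 3-phosphoglycerate branch, the reversible
hydroxymethyltransferase shuttle to glycine, the protein-synthesis drain and
the serine palmitoyltransferase entry into sphingolipids).
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fva import fba_maximize
from .model import MetabolicModel, Metabolite, Reaction, parse_gpr
from .silac import FORMULAS
from .tracer import AminoAcidPeakTable, UptakeTimecourse

__all__ = [
    "toy_network",
    "serine_toy_model",
    "simulate_peptides",
    "simulate_uptake",
    "simulate_lipid_table",
    "simulate_screen",
    "simulate_amino_acid_peaks",
    "STRAIN_INCORPORATION",
    "STRAIN_UPTAKE_RATES",
    "STRAIN_IPC_SERINE_FRACTION",
    "AMINO_ACID_LEVELS",
]

# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

#: true serine-incorporation fraction per strain (long-term heavy-serine growth)
STRAIN_INCORPORATION = {
    "WT": 0.938,
    "ser2": 0.927,
    "gnp1": 0.59,
    "agp1": 0.908,
    "gnp1agp1": 0.938 * (1 - 0.81),  # an 81% decrease from wild type
}

#: true initial serine uptake rates, nmol per mg protein per min
STRAIN_UPTAKE_RATES = {
    "WT": 1.0,
    "gnp1": 0.35,  # 65% reduction
    "agp1": 0.66,  # 34% reduction
    "gnp1agp1": 0.05,
}

#: serine-labeled IPC mole fraction of all detected lipids, per strain
STRAIN_IPC_SERINE_FRACTION = {
    "WT": 0.020,
    "gnp1": 0.020 * (1 - 0.64),
    "gnp1agp1": 0.020 * (1 - 0.73),
    "ser2": 0.024,
}

#: true amino-acid levels (nmol per 1e8 cells) per (sample, analyte)
AMINO_ACID_LEVELS = {
    ("WT_minus_serine", "serine"): 3.0,
    ("WT_plus_serine", "serine"): 3.0 * 1.67,  # 67% increase with serine fed
    ("WT_minus_serine", "glycine"): 2.0,
    ("WT_plus_serine", "glycine"): 2.0 * 2.20,  # 120% increase
    ("WT_minus_serine", "lysine"): 1.5,
    ("WT_plus_serine", "lysine"): 1.5,
    ("gnp1_minus_serine", "serine"): 3.0,
    ("gnp1_plus_serine", "serine"): 3.0,
    ("gnp1_minus_serine", "glycine"): 2.0,
    ("gnp1_plus_serine", "glycine"): 2.0,
}


def _rng(name: str, seed: int) -> np.random.Generator:
    # per-generator stream: adding a generator never perturbs the others
    return np.random.default_rng(
        [zlib.crc32(name.encode()) & 0x7FFFFFFF, int(seed) & 0x7FFFFFFF]
    )


def _write_truth(out: Path, truth: dict) -> None:
    out.with_suffix(out.suffix + ".truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# metabolic networks
# ---------------------------------------------------------------------------


def toy_network(kind: str = "chain", size: int = 6, seed: int = 0) -> MetabolicModel:
    """Small stoichiometric networks with analytically known behaviour.

    ``chain``: EX -> M1 -> ... -> biomass, optimum equal to the uptake bound
    (10).  ``parallel``: two equivalent branches, each with envelope [0, 10]
    at fraction 1.  ``yield-loss``: two routes, one wasting half its carbon.
    ``random``: a feasible random network with at most ``size`` (<= 8)
    reactions, a guaranteed nonzero optimum and all-finite bounds, suitable
    for exhaustive vertex-enumeration cross-checks.
    """
    if kind == "chain":
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
        ]
        return MetabolicModel(mets, rxns, set(), "BIOMASS")
    if kind == "parallel":
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("R1a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("R1b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
        ]
        return MetabolicModel(mets, rxns, set(), "BIOMASS")
    if kind == "yield-loss":
        # route a converts A->B 1:1; route b wastes half (2 A -> 1 B)
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("Ra", {"A": -1.0, "B": 1.0}, 0.0, 6.0),
            Reaction("Rb", {"A": -2.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
        ]
        return MetabolicModel(mets, rxns, set(), "BIOMASS")
    if kind == "random":
        if size > 8:
            raise ValueError("random networks are capped at 8 reactions")
        if size < 3:
            raise ValueError("random networks need at least 3 reactions")
        rng = _rng("toy_network", seed)
        for _ in range(100):
            model = _random_network(rng, size)
            sol = fba_maximize(model)
            if sol.optimal and sol.objective_value > 1e-6:
                return model
        raise RuntimeError("failed to draw a feasible random network")
    raise ValueError(f"unknown network kind {kind!r}")


def _random_network(rng: np.random.Generator, size: int) -> MetabolicModel:
    n_extra = size - 3  # EX + chain step(s) + biomass is the guaranteed spine
    n_mets = int(rng.integers(2, 4))
    mids = [f"M{i}" for i in range(1, n_mets + 1)]
    mets = [Metabolite(m) for m in mids]
    uptake = float(rng.integers(2, 11))
    rxns = [Reaction("EX_M1", {"M1": -1.0}, -uptake, 10.0)]
    # spine: M1 -> M2 -> ... -> Mn -> biomass
    for i in range(n_mets - 1):
        ub = float(rng.integers(3, 12))
        rxns.append(Reaction(f"C{i+1}", {mids[i]: -1.0, mids[i + 1]: 1.0}, 0.0, ub))
    rxns.append(Reaction("BIOMASS", {mids[-1]: -1.0}, 0.0, 50.0))
    n_extra = size - len(rxns)
    for j in range(max(0, n_extra)):
        i_src, i_dst = rng.choice(n_mets, size=2, replace=False)
        a = float(rng.integers(1, 3))
        b = float(rng.integers(1, 3))
        lb = float(rng.choice([-5.0, 0.0]))
        ub = float(rng.integers(1, 9))
        rxns.append(
            Reaction(f"X{j+1}", {mids[i_src]: -a, mids[i_dst]: b}, lb, ub)
        )
    return MetabolicModel(mets, rxns, set(), "BIOMASS")


def serine_toy_model() -> MetabolicModel:
    """A ~12-reaction model of the yeast serine economy.

    Serine can be imported (Gnp1/Agp1 transport of external serine) or made
    from glucose through the 3-phosphoglycerate branch (phosphoserine
    phosphatase, SER2 gene).  It is drained into protein synthesis, converted
    reversibly to glycine by the hydroxymethyltransferase shuttle (SHM1/SHM2;
    forward = serine consumption), and condensed with palmitoyl-CoA by
    serine palmitoyltransferase (LCB1/LCB2) into long-chain bases.  Biomass
    consumes protein, glycine, LCB and bulk carbohydrate.  Glucose uptake is
    capped at 2 mmol·gDW⁻¹·h⁻¹ and the carbohydrate demand keeps glucose
    fully used at optimum, so that along a serine-uptake scan (i) the net
    serine production of the synthesis reactions changes sign — synthesis
    outweighs consumption only at low serine uptake, with excess serine
    pushed to glycine at high uptake — and (ii) near the biomass floor the
    phosphoserine branch has almost no slack at high uptake, leaving the
    hydroxymethyltransferase shuttle to dominate the net envelope.
    """
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("ser_e", "serine", "e"),
        Metabolite("gly_e", "glycine", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("ser_c", "serine", "c"),
        Metabolite("gly_c", "glycine", "c"),
        Metabolite("palcoa_c", "palmitoyl-CoA", "c"),
        Metabolite("carb_c", "bulk carbohydrate", "c"),
        Metabolite("prot_c", "protein", "c"),
        Metabolite("lcb_c", "long chain base", "c"),
    ]
    g = parse_gpr
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, -2.0, 1000.0),
        Reaction("EX_ser", {"ser_e": -1.0}, 0.0, 1000.0),
        Reaction("EX_gly", {"gly_e": -1.0}, 0.0, 1000.0),
        Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
        Reaction("SERt", {"ser_e": -1.0, "ser_c": 1.0}, 0.0, 1000.0, g("GNP1 or AGP1")),
        Reaction("GLYt", {"gly_c": -1.0, "gly_e": 1.0}, 0.0, 1000.0),
        Reaction("SER2", {"glc_c": -1.0, "ser_c": 1.0}, 0.0, 1000.0, g("SER2")),
        Reaction("SHM", {"ser_c": -1.0, "gly_c": 1.0}, -1000.0, 1000.0, g("SHM1 or SHM2")),
        Reaction("FAS", {"glc_c": -1.0, "palcoa_c": 1.0}, 0.0, 1000.0),
        Reaction("CARB", {"glc_c": -1.0, "carb_c": 1.0}, 0.0, 1000.0),
        Reaction("PROT", {"ser_c": -1.0, "prot_c": 1.0}, 0.0, 1000.0),
        Reaction("SPT", {"ser_c": -1.0, "palcoa_c": -1.0, "lcb_c": 1.0}, 0.0, 1000.0,
                 g("LCB1 and LCB2")),
        Reaction(
            "BIOMASS",
            {"prot_c": -1.0, "gly_c": -0.5, "lcb_c": -0.2, "carb_c": -1.0},
            0.0,
            1000.0,
        ),
    ]
    genes = {"GNP1", "AGP1", "SER2", "SHM1", "SHM2", "LCB1", "LCB2"}
    return MetabolicModel(mets, rxns, genes, "BIOMASS")


# ---------------------------------------------------------------------------
# SILAC peptides
# ---------------------------------------------------------------------------

_AA_NO_SER = list("ACDEFGHIKLMNPQRTVWY")  # alphabet without serine


def _ratio_from_incorporation(i: np.ndarray, formula: str) -> np.ndarray:
    # inverse of the chosen per-peptide incorporation formula
    i = np.clip(i, -0.5, 0.999)
    if formula == "as-printed":
        return 1.0 + 1.0 / (1.0 - i)
    return i / (1.0 - np.clip(i, 1e-6, None))


def simulate_peptides(
    theta: float,
    n: int = 2000,
    noise_sd: float = 0.03,
    outlier_fraction: float = 0.10,
    missing_fraction: float = 0.05,
    serine_count_probs: Sequence[float] = (0.2, 0.5, 0.2, 0.1),
    formula: str = "as-printed",
    seed: int = 0,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Peptide table whose single-serine H/L ratios encode a true level theta.

    Sequences carry 0-3 serines with the given probabilities.  Single-serine
    peptides get ratios obtained by inverting the chosen incorporation
    formula at ``theta`` plus Gaussian noise; a fraction are uniform outliers
    and a fraction have their ratio blanked.  Returns (table, truth); with
    ``out`` also writes a TSV and a ``.truth.json`` sidecar.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}")
    rng = _rng("simulate_peptides", seed)
    n_ser = rng.choice(len(serine_count_probs), size=n, p=serine_count_probs)
    seqs = []
    for k in n_ser:
        length = int(rng.integers(7, 15))
        body = rng.choice(_AA_NO_SER, size=length)
        pos = rng.choice(length + 1, size=int(k), replace=False) if k else []
        seq = list(body)
        for p in sorted(pos, reverse=True):
            seq.insert(int(p), "S")
        seqs.append("".join(seq))
    inc = theta + rng.normal(0.0, noise_sd, size=n)
    is_outlier = rng.random(n) < outlier_fraction
    inc[is_outlier] = rng.uniform(0.0, 1.0, size=int(is_outlier.sum()))
    ratios = _ratio_from_incorporation(inc, formula)
    # peptides without exactly one serine get unrelated ratios
    other = n_ser != 1
    ratios[other] = rng.lognormal(mean=1.0, sigma=0.5, size=int(other.sum()))
    missing = rng.random(n) < missing_fraction
    ratios[missing] = np.nan
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "ratio_hl": ratios,
            "intensity": rng.lognormal(mean=20.0, sigma=1.0, size=n),
            "protein": [f"P{int(i):04d}" for i in rng.integers(0, max(2, n // 4), size=n)],
        }
    )
    truth = {
        "theta": theta,
        "formula": formula,
        "n": n,
        "noise_sd": noise_sd,
        "outlier_fraction": outlier_fraction,
        "missing_fraction": missing_fraction,
        "seed": seed,
    }
    if out is not None:
        out = Path(out)
        df.to_csv(out, sep="\t", index=False)
        _write_truth(out, truth)
    return df, truth


# ---------------------------------------------------------------------------
# uptake time courses
# ---------------------------------------------------------------------------


def simulate_uptake(
    rates: Mapping[str, float] | None = None,
    times: Sequence[float] = (5.0, 15.0, 30.0),
    background: float = 200.0,
    specific_activity: float = 5000.0,
    protein_mg: float = 0.1,
    replicates: int = 3,
    noise_sd: float = 0.0,
    kinetics: str = "linear",
    tau: float = 30.0,
    seed: int = 0,
    out: str | Path | None = None,
) -> tuple[list[UptakeTimecourse], dict]:
    """Scintillation time courses per strain with known true uptake rates.

    ``rates`` maps strain -> nmol per mg protein per min (defaults to the
    strain panel in :data:`STRAIN_UPTAKE_RATES`).  ``kinetics="linear"``
    accumulates rate*t; ``"saturating"`` uses rate*tau*(1-exp(-t/tau)).
    Counts are background + amount*protein*specific_activity + Gaussian
    noise, floored at zero.
    """
    rates = dict(STRAIN_UPTAKE_RATES if rates is None else rates)
    rng = _rng("simulate_uptake", seed)
    t = np.asarray(times, float)
    tcs: list[UptakeTimecourse] = []
    for strain, rate in rates.items():
        if rate < 0:
            raise ValueError("rates must be nonnegative")
        for rep in range(replicates):
            if kinetics == "linear":
                amount = rate * t  # nmol per mg protein
            elif kinetics == "saturating":
                amount = rate * tau * (1.0 - np.exp(-t / tau))
            else:
                raise ValueError(f"unknown kinetics {kinetics!r}")
            counts = background + amount * protein_mg * specific_activity
            counts = np.clip(counts + rng.normal(0.0, noise_sd, size=t.shape), 0, None)
            tcs.append(
                UptakeTimecourse(
                    strain=strain,
                    times=t,
                    counts=counts,
                    background=background,
                    protein_mg=protein_mg,
                    specific_activity=specific_activity,
                    replicate=f"r{rep+1}",
                )
            )
    truth = {
        "rates": rates,
        "times": list(map(float, t)),
        "background": background,
        "specific_activity": specific_activity,
        "protein_mg": protein_mg,
        "replicates": replicates,
        "noise_sd": noise_sd,
        "kinetics": kinetics,
        "seed": seed,
    }
    if out is not None:
        out = Path(out)
        rows = [
            {
                "strain": tc.strain,
                "replicate": tc.replicate,
                "time_min": tt,
                "counts": c,
                "background": tc.background,
                "protein_mg": tc.protein_mg,
                "specific_activity": tc.specific_activity,
            }
            for tc in tcs
            for tt, c in zip(tc.times, tc.counts)
        ]
        pd.DataFrame(rows).to_csv(out, index=False)
        _write_truth(out, truth)
    return tcs, truth


# ---------------------------------------------------------------------------
# lipid tables
# ---------------------------------------------------------------------------


def simulate_lipid_table(
    fractions: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    total_mol: float = 1.0,
    replicates: int = 2,
    counts: int | None = None,
    seed: int = 0,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Lipid-species tables with fixed labeled mole fractions per strain.

    ``fractions`` maps strain -> {(lipid_class, channel): mole fraction};
    the remainder of each sample is assigned to ("other", "unlabeled").
    With ``counts`` set, amounts are a multinomial draw of that many
    molecules around the specified fractions (scaled to ``total_mol``);
    without it, amounts equal fraction*total exactly, so the mol%
    quantification recovers the truth to machine precision.
    """
    if fractions is None:
        fractions = {
            strain: {
                ("IPC", "serine-labeled"): f,
                ("IPC", "inositol-labeled"): 0.03,
                ("IPC", "unlabeled"): 0.05,
                ("Cer", "unlabeled"): 0.02,
            }
            for strain, f in STRAIN_IPC_SERINE_FRACTION.items()
        }
    rng = _rng("simulate_lipid_table", seed)
    rows = []
    for strain, cells in fractions.items():
        fr = {k: float(v) for k, v in cells.items()}
        if any(v < 0 or v > 1 for v in fr.values()) or sum(fr.values()) > 1 + 1e-12:
            raise ValueError(f"fractions for {strain!r} must lie in [0,1] and sum <= 1")
        rest = 1.0 - sum(fr.values())
        full = dict(fr)
        if rest > 1e-12:
            full[("other", "unlabeled")] = rest
        keys = list(full)
        probs = np.array([full[k] for k in keys])
        for rep in range(replicates):
            sample = f"{strain}_r{rep+1}"
            if counts:
                draw = rng.multinomial(counts, probs / probs.sum())
                amounts = draw / counts * total_mol
            else:
                amounts = probs * total_mol
            for (cls, ch), amt in zip(keys, amounts):
                if amt > 0:
                    rows.append(
                        {
                            "sample": sample,
                            "strain": strain,
                            "lipid_class": cls,
                            "channel": ch,
                            "amount": float(amt),
                        }
                    )
    df = pd.DataFrame(rows)
    truth = {
        "fractions": {
            strain: {f"{cls}|{ch}": v for (cls, ch), v in cells.items()}
            for strain, cells in fractions.items()
        },
        "total_mol": total_mol,
        "replicates": replicates,
        "counts": counts,
        "seed": seed,
    }
    if out is not None:
        out = Path(out)
        df.to_csv(out, index=False)
        _write_truth(out, truth)
    return df, truth


# ---------------------------------------------------------------------------
# genetic-interaction screens
# ---------------------------------------------------------------------------


def simulate_screen(
    n_genes: int = 3000,
    null_sd: float = 0.05,
    planted: Sequence[tuple[str, float, float]] = (
        ("GNP1", -0.45, 1e-12),
        ("YDR509W", -0.40, 5e-12),
    ),
    seed: int = 0,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Interaction table: Gaussian null epsilons plus planted strong hits.

    Null genes draw epsilon ~ N(0, null_sd) with the exact two-sided normal
    p-value of the draw (so p is uniform under the null); planted hits are
    appended with the stated epsilon and p.
    """
    if len(planted) > n_genes:
        raise ValueError("more planted hits than genes")
    from scipy import stats

    rng = _rng("simulate_screen", seed)
    n_null = n_genes - len(planted)
    eps = rng.normal(0.0, null_sd, size=n_null)
    p = 2.0 * stats.norm.sf(np.abs(eps) / null_sd)
    df = pd.DataFrame(
        {
            "gene": [f"YNL{i:04d}" for i in range(n_null)],
            "epsilon": eps,
            "p_value": p,
        }
    )
    if planted:
        planted_df = pd.DataFrame(planted, columns=["gene", "epsilon", "p_value"])
        df = pd.concat([df, planted_df], ignore_index=True)
    truth = {
        "n_genes": n_genes,
        "null_sd": null_sd,
        "planted": [list(h) for h in planted],
        "seed": seed,
    }
    if out is not None:
        out = Path(out)
        df.to_csv(out, index=False)
        _write_truth(out, truth)
    return df, truth


# ---------------------------------------------------------------------------
# amino-acid peak tables
# ---------------------------------------------------------------------------


def simulate_amino_acid_peaks(
    levels: Mapping[tuple[str, str], float] | None = None,
    replicates: int = 3,
    noise_cv: float = 0.0,
    internal_standard_area: float = 1e6,
    calibration: Mapping[str, float] | None = None,
    cell_count: float = 1.0,
    seed: int = 0,
) -> tuple[list[AminoAcidPeakTable], dict]:
    """Peak tables whose concentrations recover known true levels.

    ``levels`` maps (sample, analyte) -> true nmol per 1e8 cells (defaults to
    :data:`AMINO_ACID_LEVELS`, the wild-type/transporter-mutant serine and
    glycine contrasts).  Areas are constructed by inverting the
    internal-standard quantification, optionally with multiplicative
    Gaussian noise of the given CV.
    """
    levels = dict(AMINO_ACID_LEVELS if levels is None else levels)
    samples = sorted({s for s, _ in levels})
    analytes = sorted({a for _, a in levels})
    calibration = dict(calibration or {a: 2.0 for a in analytes})
    rng = _rng("simulate_amino_acid_peaks", seed)
    tables: list[AminoAcidPeakTable] = []
    for sample in samples:
        for rep in range(replicates):
            areas = {}
            for analyte in analytes:
                if (sample, analyte) not in levels:
                    continue
                conc = levels[(sample, analyte)]
                noise = rng.normal(1.0, noise_cv) if noise_cv > 0 else 1.0
                areas[analyte] = (
                    conc * cell_count / calibration[analyte] * internal_standard_area
                ) * max(noise, 0.0)
            tables.append(
                AminoAcidPeakTable(
                    sample=f"{sample}_r{rep+1}",
                    areas=areas,
                    internal_standard_area=internal_standard_area,
                    calibration=calibration,
                    cell_count=cell_count,
                )
            )
    truth = {
        "levels": {f"{s}|{a}": v for (s, a), v in levels.items()},
        "replicates": replicates,
        "noise_cv": noise_cv,
        "cell_count": cell_count,
        "seed": seed,
    }
    return tables, truth
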