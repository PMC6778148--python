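"""Seeded synthetic-data generators with ground truth for every input class.

These generators emulate the data a selection campaign produces — 96-colony
Sanger runs of a BC/FG-diversified 10FN3 phagemid cassette (clone families,
reverse-orientation reads, base-call errors, truncations, invalid clones),
plate tables, and every titration type the fit engine consumes — each with
a truth record so downstream analyses can be verified end to end.  The same
(seed, parameters) always yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from fn3kit import binding
from fn3kit.clone_qc import ReadRecord
from fn3kit.library_design import NNK, expand_degenerate_codon, STOP_CODONS
from fn3kit.scaffold import ScaffoldTemplate, default_scaffold
from Bio.Seq import Seq

NNK_CODONS = [c for c, _ in expand_degenerate_codon(NNK)]
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Library reads
# ---------------------------------------------------------------------------

@dataclass
class LibraryReadsTruth:
    families: dict[int, dict[str, tuple[str, str]]]  # family -> loop -> (dna, pep)
    read_family: dict[str, int]
    planted_invalid: dict[str, list[str]]  # read id -> planted defect labels
    read_orientation: dict[str, str]


def _random_loop(rng: np.random.Generator, n_codons: int, stop_free: bool = True) -> str:
    while True:
        codons = [NNK_CODONS[i] for i in rng.integers(0, len(NNK_CODONS), n_codons)]
        if not stop_free or not any(c in STOP_CODONS for c in codons):
            return "".join(codons)


def _mutate(rng: np.random.Generator, dna: str, rate: float) -> str:
    if rate <= 0:
        return dna
    arr = np.frombuffer(dna.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def gen_library_reads(
    seed: int,
    n_reads: int = 96,
    n_families: int = 11,
    error_rate: float = 0.003,
    revcomp_fraction: float = 0.5,
    stop_clone_rate: float = 0.0,
    missing_site_rate: float = 0.0,
    truncate_rate: float = 0.0,
    bc_lengths: tuple[int, int] = (5, 9),
    fg_lengths: tuple[int, int] = (7, 13),
    scaffold: ScaffoldTemplate | None = None,
) -> tuple[list[ReadRecord], LibraryReadsTruth]:
    """Simulate a Sanger run over colonies drawn from planted clone families.

    Each family carries NNK-consistent BC (5-9 codons) and FG (7-13 codons)
    loops; every family is represented at least once and remaining reads
    are assigned uniformly.  Reads acquire per-base substitution errors,
    reverse orientation at the stated fraction, optional 5' truncation, and
    optional planted defects (in-loop stop codons, destroyed restriction
    sites) at the stated rates.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    scaffold = scaffold or default_scaffold()

    families: dict[int, dict[str, tuple[str, str]]] = {}
    peps_seen: set[str] = set()
    for fam in range(n_families):
        while True:
            bc = _random_loop(rng, int(rng.integers(bc_lengths[0], bc_lengths[1] + 1)))
            fg = _random_loop(rng, int(rng.integers(fg_lengths[0], fg_lengths[1] + 1)))
            key = str(Seq(bc).translate()) + "|" + str(Seq(fg).translate())
            if key not in peps_seen:
                peps_seen.add(key)
                break
        families[fam] = {
            "BC": (bc, str(Seq(bc).translate())),
            "FG": (fg, str(Seq(fg).translate())),
        }

    assignment = list(range(n_families)) + [
        int(rng.integers(0, n_families)) for _ in range(n_reads - n_families)
    ]

    reads: list[ReadRecord] = []
    truth = LibraryReadsTruth(families=families, read_family={},
                              planted_invalid={}, read_orientation={})
    for idx, fam in enumerate(assignment):
        read_id = f"colony{idx + 1:03d}"
        loops = {lid: families[fam][lid][0] for lid in families[fam]}
        defects: list[str] = []
        if rng.random() < stop_clone_rate:
            lid = "BC" if rng.random() < 0.5 else "FG"
            loop = loops[lid]
            pos = int(rng.integers(0, len(loop) // 3))
            loops[lid] = loop[: 3 * pos] + "TAA" + loop[3 * pos + 3:]
            defects.append("stop codon in variable region")
        dna = scaffold.with_loops(loops)
        if rng.random() < missing_site_rate:
            site = scaffold.required_sites[int(rng.integers(0, len(scaffold.required_sites)))]
            pos = dna.index(site[1])
            base = dna[pos]
            repl = "ACGT"[(("ACGT".index(base)) + 1) % 4]
            dna = dna[:pos] + repl + dna[pos + 1:]
            defects.append(f"missing required site {site[0]}")
        dna = _mutate(rng, dna, error_rate)
        if rng.random() < truncate_rate:
            dna = dna[int(rng.integers(1, 31)):]
        orientation = "reverse" if rng.random() < revcomp_fraction else "forward"
        if orientation == "reverse":
            dna = str(Seq(dna).reverse_complement())
        reads.append(ReadRecord(read_id=read_id, dna=dna))
        truth.read_family[read_id] = fam
        truth.read_orientation[read_id] = orientation
        if defects:
            truth.planted_invalid[read_id] = defects
    return reads, truth


def reads_to_fasta(reads: list[ReadRecord]) -> str:
    return "".join(f">{r.read_id}\n{r.dna}\n" for r in reads)


# ---------------------------------------------------------------------------
# Titration bundles
# ---------------------------------------------------------------------------

@dataclass
class TitrationTruth:
    sck: dict = field(default_factory=dict)
    itc: dict = field(default_factory=dict)
    fp_direct: dict = field(default_factory=dict)
    fp_competition: dict = field(default_factory=dict)
    pulldown: dict = field(default_factory=dict)


def gen_sensorgram(
    seed: int,
    kon: float = 9.5e4,
    koff: float = 0.4,
    rmax: float = 20.0,
    top_concentration: float | None = None,
    noise_ru: float = 0.0,
) -> tuple[binding.Sensorgram, dict]:
    """Single-cycle sensorgram: five two-fold ascending injections.

    The default top concentration is 10x KD so the series straddles the
    dissociation constant.
    """
    rng = np.random.default_rng(seed)
    kd = koff / kon
    top = top_concentration if top_concentration is not None else 10 * kd
    plan = binding.single_cycle_plan(top)
    sg = binding.simulate_sck(kon, koff, rmax, plan)
    if noise_ru > 0:
        sg = binding.Sensorgram(
            segments=[
                binding.Segment(s.phase, s.concentration, s.times,
                                s.response + rng.normal(0, noise_ru, len(s.response)))
                for s in sg.segments
            ],
            metadata=dict(sg.metadata),
        )
    truth = {"kon": kon, "koff": koff, "rmax": rmax, "kd": kd,
             "top_concentration": top, "noise_ru": noise_ru}
    return sg, truth


def gen_itc(
    seed: int,
    n: float = 1.0,
    kd: float = 67e-9,
    dh_kcal: float = -10.0,
    cell_concentration: float = 28e-6,
    syringe_concentration: float = 0.30e-3,
    cell_volume: float = 200e-6,
    noise_fraction: float = 0.0,
) -> tuple[binding.ItcExperiment, dict]:
    """One-set-of-sites isotherm: 0.5 uL pre-injection plus 29 x 1 uL.

    Geometry defaults follow a 200 uL cell with the binder at 28 uM and
    the titrant at 0.30 mM.  Gaussian noise scales with the largest
    injection heat.
    """
    rng = np.random.default_rng(seed)
    exp = binding.ItcExperiment(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        cell_volume=cell_volume,
        injection_volumes=binding.standard_injection_scheme(),
    )
    heats = binding.itc_isotherm(n, kd, dh_kcal, exp)
    if noise_fraction > 0:
        heats = heats + rng.normal(0, noise_fraction * np.abs(heats).max(), len(heats))
    exp.heats_ucal = heats
    truth = {"n": n, "kd": kd, "dh_kcal": dh_kcal, "noise_fraction": noise_fraction}
    return exp, truth


def gen_fp_direct(
    seed: int,
    kd: float = 1.0e-6,
    tracer: float = 50e-9,
    p_free: float = 60.0,
    p_bound: float = 220.0,
    noise_mp: float = 0.0,
    n_points: int = 12,
) -> tuple[binding.FpTitration, dict]:
    """Direct FP titration of a 50 nM fluorescent tracer."""
    rng = np.random.default_rng(seed)
    rt = np.concatenate([[0.0], np.geomspace(kd / 100, kd * 100, n_points - 1)])
    fb = binding.fp_bound_fraction(kd, rt, tracer)
    mp = p_free + (p_bound - p_free) * fb
    if noise_mp > 0:
        mp = mp + rng.normal(0, noise_mp, len(mp))
    tit = binding.FpTitration(receptor_concentrations=rt, polarization_mp=mp,
                              tracer_concentration=tracer)
    return tit, {"kd": kd, "tracer": tracer, "p_free": p_free, "p_bound": p_bound}


def gen_fp_competition(
    seed: int,
    ki: float = 2.0e-6,
    receptor_total: float = 2.0e-6,
    tracer: float = 50e-9,
    tracer_kd: float = 1.0e-6,
    p_free: float = 60.0,
    p_bound: float = 220.0,
    noise_mp: float = 0.0,
    n_points: int = 12,
    conc_range: tuple[float, float] = (1e-9, 1e-3),
) -> tuple[binding.CompetitionCurve, dict]:
    """Competitor titration against a preformed receptor-tracer complex.

    The competitor series spans a fixed assay range (1 nM to 1 mM by
    default) regardless of the planted KI, as a real titration would.
    """
    rng = np.random.default_rng(seed)
    it = np.concatenate([[0.0], np.geomspace(*conc_range, n_points - 1)])
    fb = binding.tracer_bound_fraction_competition(receptor_total, tracer, it,
                                                   tracer_kd, ki)
    mp = p_free + (p_bound - p_free) * fb
    if noise_mp > 0:
        mp = mp + rng.normal(0, noise_mp, len(mp))
    curve = binding.CompetitionCurve(
        competitor_concentrations=it, signal=mp, receptor_total=receptor_total,
        tracer_total=tracer, tracer_kd=tracer_kd,
    )
    return curve, {"ki": ki}


def gen_pulldown(
    seed: int,
    ki: float = 0.5e-6,
    receptor_total: float = 0.9e-6,
    tracer: float = 0.6e-6,
    tracer_kd: float = 0.6e-6,
    noise_fraction: float = 0.05,
    n_points: int = 8,
    n_replicates: int = 2,
) -> tuple[binding.CompetitionCurve, dict]:
    """Densitometry of a competitive pull-down, duplicate lanes, % of lane 0.

    The non-competed band intensity follows the ternary-equilibrium tracer
    bound fraction; replicate lanes carry independent multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    conc = np.concatenate([[0.0], np.geomspace(ki / 30, ki * 300, n_points - 1)])
    fb = binding.tracer_bound_fraction_competition(receptor_total, tracer, conc,
                                                   tracer_kd, ki)
    rel = fb / fb[0]
    lanes_c, lanes_y = [], []
    for _ in range(n_replicates):
        noisy = rel * (1 + rng.normal(0, noise_fraction, len(rel)))
        lanes_c.append(conc)
        lanes_y.append(100.0 * noisy)
    curve = binding.CompetitionCurve(
        competitor_concentrations=np.concatenate(lanes_c),
        signal=np.concatenate(lanes_y),
        receptor_total=receptor_total, tracer_total=tracer, tracer_kd=tracer_kd,
    )
    return curve, {"ki": ki, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# Selection fixtures
# ---------------------------------------------------------------------------

def gen_serial_dilution_counts(
    seed: int,
    true_titer: float = 1e8,
    dilutions: tuple[float, ...] = (1e4, 1e5, 1e6),
    plated_volume_ml: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Poisson colony counts from plating a serial dilution series."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in dilutions:
        lam = true_titer * plated_volume_ml / d
        rows.append({"dilution": d, "volume_ml": plated_volume_ml,
                     "colonies": int(rng.poisson(lam))})
    return pd.DataFrame(rows), {"true_titer": true_titer}


def gen_elisa_plate(
    seed: int,
    clones: tuple[str, ...] = ("cloneA", "cloneB"),
    targets: tuple[str, ...] = ("PSD-95-12", "SAP97-12", "SAP102-12", "PSD-93-12"),
    primary: str = "PSD-95-12",
    selectivity: float = 10.0,
    primary_signal: float = 1.0,
    blank_od: float = 0.08,
    noise_fraction: float = 0.02,
    n_blanks: int = 4,
):
    """OD450 plate with planted fold-selectivity for the primary target."""
    from fn3kit.selection import ElisaPlate

    rng = np.random.default_rng(seed)
    data = {}
    for t in targets:
        base = primary_signal if t == primary else primary_signal / selectivity
        data[t] = blank_od + base * (1 + rng.normal(0, noise_fraction, len(clones)))
    od = pd.DataFrame(data, index=list(clones))
    blanks = pd.DataFrame(
        {t: blank_od * (1 + rng.normal(0, noise_fraction, n_blanks)) for t in targets},
        index=[f"BLANK{i + 1}" for i in range(n_blanks)],
    )
    plate = ElisaPlate(od450=od, blanks=blanks)
    return plate, {"selectivity": selectivity, "primary": primary}


def gen_panning_series(
    seed: int,
    n_rounds: int = 3,
    schedule_nm: tuple[float, ...] = (100.0, 50.0, 25.0),
    start_ratio: float = 1.5,
    growth: float = 8.0,
    control_titer: float = 1e5,
) -> tuple[list, dict]:
    """Panning rounds with a binder population growing round over round."""
    from fn3kit.selection import PanningRound

    rng = np.random.default_rng(seed)
    rounds = []
    for i in range(n_rounds):
        ratio = start_ratio * growth ** i
        target = control_titer * ratio * (1 + 0.05 * rng.standard_normal())
        rounds.append(PanningRound(
            round_index=i + 1,
            target_concentration_nM=schedule_nm[i] if i < len(schedule_nm) else schedule_nm[-1],
            eluted_target_titer=float(max(target, 0)),
            eluted_control_titer=control_titer,
        ))
    return rounds, {"growth": growth}


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

def gen_shift_tables(
    seed: int,
    n_residues: int = 120,
    first_residue: int = 61,
    patch_start: int = 115,
    patch_len: int = 12,
    n_amplitude_ppm: float = 1.2,
    h_amplitude_ppm: float = 0.25,
    broadened: tuple[int, ...] = (),
    missing: tuple[int, ...] = (),
    noise_ppm: float = 0.004,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Free/bound amide shift tables with a contiguous planted epitope patch.

    Baseline shifts are drawn from typical amide ranges; residues in the
    patch move by the stated 15N/1H amplitudes (scaled by a per-residue
    profile peaking mid-patch), the rest jitter at ``noise_ppm``.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    residues = np.arange(first_residue, first_residue + n_residues)
    resnames = rng.choice(list("ACDEFGHIKLMNQRSTVWY"), n_residues)
    h_free = rng.uniform(7.0, 9.5, n_residues)
    n_free = rng.uniform(105.0, 130.0, n_residues)

    patch = set(range(patch_start, patch_start + patch_len))
    profile = {}
    for k, res in enumerate(sorted(patch)):
        x = (k + 0.5) / patch_len
        profile[res] = 0.5 + 0.5 * math.sin(math.pi * x)  # 0.5..1.0, peak mid-patch

    h_bound = h_free + rng.normal(0, noise_ppm, n_residues)
    n_bound = n_free + rng.normal(0, noise_ppm, n_residues)
    for i, res in enumerate(residues):
        if res in patch:
            sign_h = 1 if rng.random() < 0.5 else -1
            sign_n = 1 if rng.random() < 0.5 else -1
            h_bound[i] += sign_h * h_amplitude_ppm * profile[res]
            n_bound[i] += sign_n * n_amplitude_ppm * profile[res]

    def table(h, n, flag_broadened: bool) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": residues,
            "resname": resnames,
            "h_ppm": h,
            "n_ppm": n,
            "broadened": [flag_broadened and (r in broadened) for r in residues],
            "missing": [r in missing for r in residues],
        })

    free = table(h_free, n_free, flag_broadened=False)
    bound = table(h_bound, n_bound, flag_broadened=True)
    truth = {"patch": sorted(patch & set(residues.tolist())),
             "broadened": sorted(set(broadened) & set(residues.tolist())),
             "missing": sorted(set(missing) & set(residues.tolist()))}
    return free, bound, truth
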