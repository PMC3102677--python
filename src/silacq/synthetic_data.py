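"""Ground-truthed synthetic SILAC experiments.

Emulates the study design this pipeline targets: four sample types —
forward mixed (light resistant : heavy parental), reverse mixed, and the
two self-mixed controls — each in biological triplicate analyzed in
technical duplicate (24 LC-MS runs), mixed 1:1, with a minority of
proteins carrying true fold changes.

Each detected peptide is emitted as a pair of Gaussian elution profiles
(light and heavy channel) sampled at the scan interval, in a per-scan
detection-table dialect (run id, retention time, neutral monoisotopic
mass, charge, area), plus a peptide-identification table subsampled at a
configurable rate.  Noise knobs cover ppm-scale mass error, minute-scale
retention-time jitter, log-normal channel area noise, per-biological-
replicate ratio noise, and missing observations.  With every noise scale
at zero the emitted areas encode the true relative isotope abundance
exactly, which downstream tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_chem import LabelScheme, digest, mz

__all__ = [
    "MIX_FWD",
    "MIX_REV",
    "CTRL_CDDP",
    "CTRL_HELA",
    "MIXED_TYPES",
    "CONTROL_TYPES",
    "SAMPLE_TYPES",
    "SimConfig",
    "GroundTruth",
    "Experiment",
    "simulate_proteome",
    "simulate_experiment",
    "simulate",
    "build_manifest",
    "write_experiment",
    "read_detections",
    "read_identifications",
    "read_manifest",
    "write_fasta",
    "read_fasta",
]

MIX_FWD = "mix_fwd"  # light resistant : heavy parental
MIX_REV = "mix_rev"  # heavy resistant : light parental
CTRL_CDDP = "ctrl_cddp"  # resistant mixed with itself
CTRL_HELA = "ctrl_hela"  # parental mixed with itself

MIXED_TYPES = (MIX_FWD, MIX_REV)
CONTROL_TYPES = (CTRL_CDDP, CTRL_HELA)
SAMPLE_TYPES = MIXED_TYPES + CONTROL_TYPES

_ORIENTATION = {MIX_FWD: "forward", MIX_REV: "reverse", CTRL_CDDP: "none", CTRL_HELA: "none"}

# residues used to fill tryptic segments (no K/R/P, so cleavage sites are
# exactly the appended K/R terminators)
_FILL_RESIDUES = np.array(list("GASTVLINDQEMHFYW"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated SILAC experiment."""

    n_proteins: int = 200
    seq_length: tuple[int, int] = (60, 120)
    frac_up: float = 0.1
    frac_down: float = 0.1
    #: log-scale location/scale of true fold changes for changed proteins
    fold_log_mu: float = math.log(2.0)
    fold_log_sigma: float = 0.25
    fold_cap: float = 4.5
    sigma_bio: float = 0.1
    sigma_tech: float = 0.05
    ppm_sigma: float = 1.0
    rt_jitter: float = 0.5
    rt_range: tuple[float, float] = (12.0, 110.0)
    detect_prob: float = 0.85
    id_prob: float = 0.6
    #: fraction of peptides whose reference RT falls in the wash window
    wash_frac: float = 0.02
    wash_end: float = 10.0
    gradient_end: float = 120.0
    mz_window: tuple[float, float] = (400.0, 1400.0)
    #: fraction of digestible missed-cleavage peptides that are observable
    missed_cleavage_frac: float = 0.15
    trace_sd_range: tuple[float, float] = (0.1, 0.3)
    scan_interval_s: float = 2.0
    trace_halfwidth_sigmas: float = 2.5
    n_bio: int = 3
    n_tech: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not (0 <= self.frac_up and 0 <= self.frac_down):
            raise ValueError("frac_up/frac_down must be >= 0")
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("frac_up + frac_down must be < 1")
        for name in ("sigma_bio", "sigma_tech", "ppm_sigma", "rt_jitter", "wash_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("detect_prob", "id_prob"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        lo, hi = self.rt_range
        if not (0 <= lo < hi <= self.gradient_end):
            raise ValueError("rt_range must lie within (0, gradient_end)")

    @property
    def scan_interval_min(self) -> float:
        return self.scan_interval_s / 60.0

    @property
    def n_runs(self) -> int:
        return len(SAMPLE_TYPES) * self.n_bio * self.n_tech


@dataclass
class GroundTruth:
    """True simulation state: proteins, observable peptides, run design."""

    proteins: pd.DataFrame  # accession, sequence, rho, direction
    peptides: pd.DataFrame  # accession, sequence, charge, n_K, n_R, masses, ref_rt, ...
    manifest: pd.DataFrame  # run_id, sample_type, orientation, bio_rep, tech_rep
    config: SimConfig


@dataclass
class Experiment:
    """Simulated per-run detection and identification tables."""

    detections: pd.DataFrame  # run_id, rt_min, mono_mass_da, charge, area
    identifications: pd.DataFrame  # run_id, sequence, charge, mono_mass_da, rt_min, score, accession
    manifest: pd.DataFrame
    truth: GroundTruth


def build_manifest(config: SimConfig) -> pd.DataFrame:
    rows = []
    for stype in SAMPLE_TYPES:
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                rows.append(
                    {
                        "run_id": f"{stype}_b{b}_t{t}",
                        "sample_type": stype,
                        "orientation": _ORIENTATION[stype],
                        "bio_rep": b,
                        "tech_rep": t,
                    }
                )
    return pd.DataFrame(rows)


def _random_protein(rng: np.random.Generator, target_len: int) -> str:
    # tryptic segments of 5-14 filler residues terminated by K or R; the
    # final segment is left unterminated (a zero-label C-terminal peptide)
    parts: list[str] = []
    total = 0
    while total < target_len:
        k = int(rng.integers(5, 15))
        seg = "".join(rng.choice(_FILL_RESIDUES, size=k))
        term = "K" if rng.random() < 0.5 else "R"
        parts.append(seg + term)
        total += k + 1
    tail = "".join(rng.choice(_FILL_RESIDUES, size=int(rng.integers(4, 9))))
    return "".join(parts) + tail


def simulate_proteome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Generate a random proteome with designated up/down proteins.

    Returns FASTA records ``(accession, sequence)`` and the ground truth.
    True fold changes rho are resistant:parental ratios; unchanged
    proteins have rho exactly 1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_proteins
    lo, hi = config.seq_length

    records = []
    for i in range(n):
        acc = f"P{i:05d}"
        records.append((acc, _random_protein(rng, int(rng.integers(lo, hi + 1)))))

    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    changed = rng.choice(n, size=n_up + n_down, replace=False)
    rho = np.ones(n)
    if n_up + n_down:
        mags = np.exp(rng.normal(config.fold_log_mu, config.fold_log_sigma, n_up + n_down))
        mags = np.clip(mags, 1.25, config.fold_cap)
        rho[changed[:n_up]] = mags[:n_up]
        rho[changed[n_up:]] = 1.0 / mags[n_up:]
    direction = np.where(rho > 1, "up", np.where(rho < 1, "down", "unchanged"))

    proteins = pd.DataFrame(
        {
            "accession": [a for a, _ in records],
            "sequence": [s for _, s in records],
            "rho": rho,
            "direction": direction,
        }
    )
    peptides = _observable_peptides(proteins, config, rng)
    truth = GroundTruth(proteins, peptides, build_manifest(config), config)
    return records, truth


def _observable_peptides(
    proteins: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    scheme = LabelScheme()
    rows = []
    for acc, seq in zip(proteins["accession"], proteins["sequence"]):
        for pep in digest(seq, max_missed=1, scheme=scheme):
            if not 1 <= pep.n_labels <= 2:
                continue
            if not 6 <= len(pep.sequence) <= 30:
                continue
            if pep.missed_cleavages == 1 and rng.random() >= config.missed_cleavage_frac:
                continue
            charge = 2 if pep.mass_light <= 2800 else 3
            mz_light = mz(pep.mass_light, charge)
            if not config.mz_window[0] <= mz_light <= config.mz_window[1]:
                continue
            rows.append(
                {
                    "accession": acc,
                    "sequence": pep.sequence,
                    "charge": charge,
                    "n_K": pep.n_labeled_K,
                    "n_R": pep.n_labeled_R,
                    "mass_light": pep.mass_light,
                    "mass_heavy": pep.mass_heavy,
                }
            )
    peps = pd.DataFrame(rows)
    if peps.empty:
        raise ValueError("proteome produced no observable labeled peptides")
    # shared sequences would make accession assignment ambiguous; drop them
    peps = peps.drop_duplicates("sequence", keep=False).reset_index(drop=True)

    m = len(peps)
    rt_lo, rt_hi = config.rt_range
    ref_rt = rng.uniform(rt_lo, rt_hi, m)
    in_wash = rng.random(m) < config.wash_frac
    ref_rt[in_wash] = rng.uniform(0.5, config.wash_end - 0.5, int(in_wash.sum()))
    peps["ref_rt"] = ref_rt
    peps["base_area"] = np.exp(rng.normal(np.log(1e5), 1.0, m))
    peps["trace_sd"] = rng.uniform(*config.trace_sd_range, m)
    return peps


def simulate_experiment(
    truth: GroundTruth, rng: np.random.Generator | None = None
) -> Experiment:
    """Emit per-run detection and identification tables for a proteome."""
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    peps = truth.peptides
    if peps.empty:
        raise ValueError("no digestible peptides to simulate")
    manifest = truth.manifest
    n_pep = len(peps)
    n_runs = len(manifest)

    acc_index = pd.Index(truth.proteins["accession"])
    pep_prot = acc_index.get_indexer(peps["accession"])
    rho = truth.proteins["rho"].to_numpy()

    # biological ratio noise: one draw per (protein, sample_type, bio_rep),
    # shared across that replicate's technical duplicates
    stype_idx = {s: i for i, s in enumerate(SAMPLE_TYPES)}
    eps_bio = rng.normal(0.0, config.sigma_bio, (len(rho), len(SAMPLE_TYPES), config.n_bio))

    # per-run, per-peptide quantities, shape (n_pep, n_runs)
    ria = np.empty((n_pep, n_runs))
    for r, row in enumerate(manifest.itertuples(index=False)):
        s = stype_idx[row.sample_type]
        eps = eps_bio[pep_prot, s, row.bio_rep - 1]
        base = rho[pep_prot] if row.sample_type in MIXED_TYPES else 1.0
        rho_eff = base * np.exp(eps)
        if row.orientation == "reverse":
            ria[:, r] = 1.0 / (1.0 + rho_eff)
        else:
            ria[:, r] = rho_eff / (1.0 + rho_eff)

    detected = rng.random((n_pep, n_runs)) < config.detect_prob
    rt_run = peps["ref_rt"].to_numpy()[:, None] + rng.normal(0.0, config.rt_jitter, (n_pep, n_runs))
    # keep the whole elution trace at positive RT
    rt_floor = config.trace_halfwidth_sigmas * peps["trace_sd"].to_numpy() + 0.01
    rt_run = np.maximum(rt_run, rt_floor[:, None])
    base = peps["base_area"].to_numpy()[:, None]
    area_light = base * ria * np.exp(rng.normal(0.0, config.sigma_tech, (n_pep, n_runs)))
    area_heavy = base * (1.0 - ria) * np.exp(rng.normal(0.0, config.sigma_tech, (n_pep, n_runs)))
    ppm = config.ppm_sigma * 1e-6
    mass_l = peps["mass_light"].to_numpy()[:, None] * (1.0 + rng.normal(0.0, ppm, (n_pep, n_runs)))
    mass_h = peps["mass_heavy"].to_numpy()[:, None] * (1.0 + rng.normal(0.0, ppm, (n_pep, n_runs)))

    pep_i, run_i = np.nonzero(detected)
    detections = _emit_traces(
        config, peps, pep_i, run_i, rt_run, mass_l, mass_h, area_light, area_heavy, manifest
    )

    identified = rng.random(pep_i.shape) < config.id_prob
    idp, idr = pep_i[identified], run_i[identified]
    identifications = pd.DataFrame(
        {
            "run_id": manifest["run_id"].to_numpy()[idr],
            "sequence": peps["sequence"].to_numpy()[idp],
            "charge": peps["charge"].to_numpy()[idp],
            "mono_mass_da": mass_l[idp, idr],
            "rt_min": rt_run[idp, idr],
            "score": rng.uniform(20.0, 120.0, idp.size),
            "accession": peps["accession"].to_numpy()[idp],
        }
    )
    return Experiment(detections, identifications, manifest, truth)


def _emit_traces(config, peps, pep_i, run_i, rt_run, mass_l, mass_h, area_l, area_h, manifest):
    """Expand (peptide, run, channel) features into per-scan Gaussian rows."""
    dt = config.scan_interval_min
    # one feature per channel; order: all light then all heavy
    n_feat = 2 * pep_i.size
    f_pep = np.concatenate([pep_i, pep_i])
    f_run = np.concatenate([run_i, run_i])
    f_mass = np.concatenate([mass_l[pep_i, run_i], mass_h[pep_i, run_i]])
    f_area = np.concatenate([area_l[pep_i, run_i], area_h[pep_i, run_i]])
    f_rt = rt_run[np.concatenate([pep_i, pep_i]), np.concatenate([run_i, run_i])]
    f_sd = peps["trace_sd"].to_numpy()[f_pep]
    f_charge = peps["charge"].to_numpy()[f_pep]

    n_half = np.floor(config.trace_halfwidth_sigmas * f_sd / dt).astype(np.int64)
    n_scans = 2 * n_half + 1
    starts = np.concatenate([[0], np.cumsum(n_scans)[:-1]])
    total = int(n_scans.sum())
    row_feat = np.repeat(np.arange(n_feat), n_scans)
    offsets = (np.arange(total) - starts[row_feat] - n_half[row_feat]) * dt
    sd_rows = f_sd[row_feat]
    heights = np.exp(-0.5 * (offsets / sd_rows) ** 2)
    # scale so the discrete trapezoid of the trace equals the target area
    h_sum = np.add.reduceat(heights, starts)
    h_edge = heights[starts]  # symmetric: first == last
    trapz = dt * (h_sum - h_edge)
    single = n_scans == 1
    scale = np.where(single, f_area, f_area / np.where(trapz > 0, trapz, 1.0))
    run_ids = manifest["run_id"].to_numpy()
    return pd.DataFrame(
        {
            "run_id": pd.Categorical.from_codes(f_run[row_feat], categories=list(run_ids)),
            "rt_min": f_rt[row_feat] + offsets,
            "mono_mass_da": f_mass[row_feat],
            "charge": f_charge[row_feat],
            "area": heights * scale[row_feat],
        }
    ).astype({"run_id": str})


def simulate(config: SimConfig | None = None) -> Experiment:
    """Proteome + experiment in one call, reproducible under the seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    _, truth = simulate_proteome(config, rng)
    return simulate_experiment(truth, rng)


# ---------------------------------------------------------------------------
# plain-text I/O

def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    acc, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if acc is not None:
                    records.append((acc, "".join(chunks)))
                acc, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if acc is not None:
        records.append((acc, "".join(chunks)))
    return records


def write_experiment(exp: Experiment, outdir: str | Path) -> None:
    """Write detection/identification/manifest/truth tables and the FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.detections.to_csv(outdir / "detections.tsv", sep="\t", index=False)
    exp.identifications.to_csv(outdir / "identifications.csv", index=False)
    exp.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth = exp.truth
    truth.proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t", index=False)
    truth.peptides.to_csv(outdir / "truth_peptides.tsv", sep="\t", index=False)
    write_fasta(list(zip(truth.proteins["accession"], truth.proteins["sequence"])), outdir / "proteome.fasta")


def read_detections(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"run_id": str})


def read_identifications(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"run_id": str, "sequence": str})


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"run_id": str})
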