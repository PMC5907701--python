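"""Seeded synthetic proteins for end-to-end testing without downloads.

The generator emulates what the pipeline sees in practice: a beta-strand
topology (strand segments plus a connected set of parallel/antiparallel
pairings), the implied ground-truth beta-beta contacts, a noisy contact map
in which each contact contributes a small Gaussian bump (so contact runs
form genuine ridges over a noise background, alongside decoy ridge
segments), and an imperfect 3-state secondary-structure profile.

Defaults emulate the noisy-coevolution regime: signal bumps of amplitude
0.8 and std 1 cell over an |N(0, 0.4)| background, 6 decoy segments at
comparable brightness, and a secondary-structure profile whose argmax
matches the truth at 80% of residues (comparable to a modern 3-state
predictor's E-state accuracy).  All randomness derives from one master seed
via named child streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence
from zlib import crc32

import numpy as np
import yaml

from .io import (
    ContactMap,
    LabelSet,
    SecondaryStructureProfile,
    write_contact_map,
    write_labels,
    write_ss,
)

__all__ = [
    "SyntheticProtein",
    "generate_topology",
    "generate_contact_map",
    "corrupt_ss_profile",
    "generate_protein",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_SIGNAL = 0.8
DEFAULT_NOISE_SCALE = 0.4
DEFAULT_RIDGE_STD = 1.0
DEFAULT_N_DECOYS = 6
DEFAULT_SS_ACCURACY = 0.8
DEFAULT_SS_SHARPNESS = 6.0


def _child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Named child stream of the master seed (stable across runs)."""
    entropy = [int(seed)] + [crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SyntheticProtein:
    name: str
    length: int
    ss_truth: str
    strands: list
    pairings: list          # (strand_a, strand_b, orientation, offset)
    truth: LabelSet
    cmap: ContactMap
    ss_profile: SecondaryStructureProfile
    n_seqs: int


# ---------------------------------------------------------------------------
# topology


def _pairing_contacts(strand_a, strand_b, orientation: str, offset: int) -> set:
    """Contacts implied by one strand pairing.

    Antiparallel pairing of A=(a1..a2) with B=(b1..b2) at register offset r
    gives (a1+k, b2-k-r); parallel gives (a1+k, b1+k+r); only in-range
    residue pairs are kept.
    """
    a1, a2 = strand_a
    b1, b2 = strand_b
    contacts = set()
    for k in range(a2 - a1 + 1):
        if orientation == "antiparallel":
            partner = b2 - k - offset
        else:
            partner = b1 + k + offset
        if b1 <= partner <= b2:
            i, j = a1 + k, partner
            contacts.add((min(i, j), max(i, j)))
    return contacts


def generate_topology(L: int, n_strands: int, seed: int):
    """Random beta topology: strands, pairings and the implied contacts.

    Strands are 3-8 residues long, separated by at least 2 coil residues;
    the pairing graph is a random spanning path (so it is connected) with
    occasional extra pairings, keeping each strand with 1-2 partners.
    """
    if L < 30:
        raise ValueError("need L >= 30")
    if not 2 <= n_strands <= L // 6:
        raise ValueError("need 2 <= n_strands <= L // 6")
    rng = _child_rng(seed, "topology")
    for _attempt in range(50):
        lengths = rng.integers(3, 9, size=n_strands)
        gaps_needed = 2 * (n_strands - 1)
        slack = L - int(lengths.sum()) - gaps_needed
        if slack < 2:
            continue
        # distribute slack among the n_strands+1 gaps (ends included)
        cuts = np.sort(rng.integers(0, slack + 1, size=n_strands))
        extras = np.diff(np.concatenate([[0], cuts, [slack]]))
        strands = []
        pos = int(extras[0])
        for s_len, extra in zip(lengths, extras[1:]):
            strands.append((pos, pos + int(s_len) - 1))
            pos += int(s_len) + 2 + int(extra)
        if strands[-1][1] >= L:
            continue

        order = rng.permutation(n_strands)
        pairings = []
        partner_count = np.zeros(n_strands, dtype=int)
        contacts: set = set()
        ok = True
        for a, b in zip(order, order[1:]):
            orientation = "antiparallel" if rng.random() < 0.7 else "parallel"
            offset = int(rng.integers(-1, 2))
            sa, sb = (a, b) if strands[a][0] < strands[b][0] else (b, a)
            c = _pairing_contacts(strands[sa], strands[sb], orientation, offset)
            c = {p for p in c if p[1] - p[0] >= 3}
            if len(c) < 2:
                c = _pairing_contacts(strands[sa], strands[sb], orientation, 0)
                c = {p for p in c if p[1] - p[0] >= 3}
                offset = 0
            if len(c) < 2:
                ok = False
                break
            pairings.append((int(sa), int(sb), orientation, offset))
            partner_count[[sa, sb]] += 1
            contacts |= c
        if not ok:
            continue
        ss = ["C"] * L
        for a, b in strands:
            for r in range(a, b + 1):
                ss[r] = "E"
        # occasional helix in a long coil stretch, for SS-feature realism
        coil_runs = []
        start = None
        for k in range(L):
            if ss[k] == "C" and start is None:
                start = k
            elif ss[k] != "C" and start is not None:
                coil_runs.append((start, k - 1))
                start = None
        if start is not None:
            coil_runs.append((start, L - 1))
        for a, b in coil_runs:
            # leave at least one coil residue on each side of an added helix
            if b - a - 1 >= 4 and rng.random() < 0.5:
                h_len = int(rng.integers(4, min(8, b - a - 1) + 1))
                h_start = int(rng.integers(a + 1, b - h_len + 1))
                for r in range(h_start, h_start + h_len):
                    ss[r] = "H"
        truth = LabelSet(contacts=contacts, strands=strands)
        return "".join(ss), strands, pairings, truth
    raise RuntimeError(f"could not pack {n_strands} strands into L={L}")


# ---------------------------------------------------------------------------
# contact map


def generate_contact_map(
    truth: LabelSet,
    L: int,
    signal: float = DEFAULT_SIGNAL,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    n_decoys: int = DEFAULT_N_DECOYS,
    ridge_std: float = DEFAULT_RIDGE_STD,
    seed: int = 0,
    n_seqs: Optional[int] = None,
) -> ContactMap:
    """Noisy contact map with ridge-like signal at the truth contacts.

    Background is the absolute value of centred Gaussian noise; each truth
    contact adds an isotropic Gaussian bump (amplitude ``signal``, std
    ``ridge_std``), so contact runs form genuine ridges whose ground-truth
    width is ``ridge_std``.  ``n_decoys`` short diagonal/anti-diagonal decoy
    segments of comparable brightness are added away from the truth set so
    that brightness alone cannot separate signal from noise.
    """
    if signal <= 0:
        raise ValueError("signal must be positive")
    rng = _child_rng(seed, "map")
    if noise_scale > 0:
        mat = np.abs(rng.normal(0.0, noise_scale, size=(L, L)))
        mat = 0.5 * (mat + mat.T)
    else:
        mat = np.zeros((L, L))

    def bump(i: int, j: int, amp: float):
        r = int(np.ceil(4 * ridge_std))
        x0, x1 = max(0, i - r), min(L, i + r + 1)
        y0, y1 = max(0, j - r), min(L, j + r + 1)
        x = np.arange(x0, x1) - i
        y = np.arange(y0, y1) - j
        mat[x0:x1, y0:y1] += amp * np.exp(
            -0.5 * (x[:, None] ** 2 + y[None, :] ** 2) / ridge_std**2
        )

    for i, j in truth.contacts:
        bump(i, j, signal)
        bump(j, i, signal)

    truth_arr = np.array(sorted(truth.contacts)) if truth.contacts else np.empty((0, 2))
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < 200:
        attempts += 1
        ci = int(rng.integers(3, L - 3))
        cj = int(rng.integers(3, L - 3))
        if abs(ci - cj) < 5:
            continue
        step = (1, 1) if rng.random() < 0.5 else (1, -1)
        length = int(rng.integers(3, 6))
        cells = [(ci + k * step[0], cj + k * step[1]) for k in range(length)]
        if any(not (0 <= a < L and 0 <= b < L) for a, b in cells):
            continue
        if truth_arr.size and any(
            np.min(np.abs(truth_arr - np.array([min(a, b), max(a, b)])).max(axis=1)) <= 2
            for a, b in cells
        ):
            continue
        for a, b in cells:
            bump(a, b, 0.8 * signal)
            bump(b, a, 0.8 * signal)
        placed += 1

    mat = np.clip(0.5 * (mat + mat.T), 0.0, None)
    np.fill_diagonal(mat, 0.0)
    return ContactMap(mat, n_seqs=n_seqs)


# ---------------------------------------------------------------------------
# secondary structure corruption


def corrupt_ss_profile(
    ss_truth: str,
    accuracy: float = DEFAULT_SS_ACCURACY,
    sharpness: float = DEFAULT_SS_SHARPNESS,
    seed: int = 0,
) -> SecondaryStructureProfile:
    """Soft 3-state profile whose argmax matches the truth with probability
    ``accuracy`` per residue.

    The winning state receives mass ``sharpness`` on top of a flat Dirichlet
    draw, so the argmax is the winner by construction (``sharpness >= 1``)
    and the profile hardens to one-hot as ``sharpness`` grows.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must lie in (0, 1]")
    if sharpness < 1.0:
        raise ValueError("sharpness must be >= 1")
    rng = _child_rng(seed, "ss")
    L = len(ss_truth)
    probs = rng.dirichlet(np.ones(3), size=L)
    winners = np.array(["HEC".index(s) for s in ss_truth])
    wrong = rng.random(L) >= accuracy
    if np.any(wrong):
        shift = rng.integers(1, 3, size=int(wrong.sum()))
        winners[wrong] = (winners[wrong] + shift) % 3
    probs[np.arange(L), winners] += sharpness
    probs /= probs.sum(axis=1, keepdims=True)
    return SecondaryStructureProfile(probs)


# ---------------------------------------------------------------------------
# whole proteins and datasets


def generate_protein(
    name: str,
    L: int,
    seed: int,
    n_strands: Optional[int] = None,
    signal: float = DEFAULT_SIGNAL,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    n_decoys: int = DEFAULT_N_DECOYS,
    ridge_std: float = DEFAULT_RIDGE_STD,
    ss_accuracy: float = DEFAULT_SS_ACCURACY,
    ss_sharpness: float = DEFAULT_SS_SHARPNESS,
) -> SyntheticProtein:
    rng = _child_rng(seed, "protein", name)
    if n_strands is None:
        hi = max(2, min(7, L // 12))
        lo = min(4, hi)
        n_strands = int(rng.integers(lo, hi + 1))
    n_seqs = int(np.round(float(rng.lognormal(np.log(2.0 * L), 1.0))))
    n_seqs = int(np.clip(n_seqs, 20, 50000))
    sub = int(rng.integers(0, 2**31 - 1))
    ss_truth, strands, pairings, truth = generate_topology(L, n_strands, sub)
    cmap = generate_contact_map(
        truth, L, signal=signal, noise_scale=noise_scale, n_decoys=n_decoys,
        ridge_std=ridge_std, seed=sub, n_seqs=n_seqs,
    )
    ss_profile = corrupt_ss_profile(
        ss_truth, accuracy=ss_accuracy, sharpness=ss_sharpness, seed=sub
    )
    return SyntheticProtein(
        name=name, length=L, ss_truth=ss_truth, strands=strands,
        pairings=pairings, truth=truth, cmap=cmap, ss_profile=ss_profile,
        n_seqs=n_seqs,
    )


def generate_dataset(
    n: int,
    L_range=(60, 120),
    seed: int = 0,
    prefix: str = "syn",
    **params,
) -> list:
    """``n`` independent synthetic proteins with lengths uniform in
    ``L_range``; per-protein streams are derived from the master seed so the
    set is reproducible and no two proteins share a map."""
    rng = _child_rng(seed, "dataset")
    out = []
    for k in range(n):
        L = int(rng.integers(L_range[0], L_range[1] + 1))
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(generate_protein(f"{prefix}{k:03d}", L, seed=sub, **params))
    return out


def write_dataset(proteins: Sequence[SyntheticProtein], outdir) -> Path:
    """Write maps, SS profiles, truth strings and labels plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in proteins:
        write_contact_map(p.cmap, outdir / f"{p.name}.map")
        write_ss(p.ss_profile, outdir / f"{p.name}.ss")
        (outdir / f"{p.name}.dssp").write_text(p.ss_truth + "\n")
        write_labels(p.truth, outdir / f"{p.name}.labels")
        entries.append(
            {
                "name": p.name,
                "length": p.length,
                "n_seqs": p.n_seqs,
                "map": f"{p.name}.map",
                "ss": f"{p.name}.ss",
                "dssp": f"{p.name}.dssp",
                "labels": f"{p.name}.labels",
            }
        )
    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"proteins": entries}, fh, sort_keys=False)
    return manifest
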