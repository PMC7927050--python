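"""Regenerate the bundled signature catalogs and the ID83 bin table.

The bundled catalogs are synthetic stand-ins with the real catalogs'
shape (SBS96 / ID83 categories, unit-sum profiles) and qualitative
character (SBS1 CpG C>T concentrated, SBS5 flat, SBS15/21 substitution-
type biased, ID1/ID2 homopolymer-insertion/deletion dominated). They are
deterministic; this script is committed so the frozen TSVs under
src/serrata/data/ can be reproduced exactly.

Usage: python scripts/make_bundled_catalogs.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from serrata.mutational_profile import ID83_CATEGORIES, SBS96_CATEGORIES

OUT = Path(__file__).resolve().parent.parent / "src" / "serrata" / "data"


def _mass(categories, weights: dict[str, float], noise: float, rng) -> np.ndarray:
    v = np.zeros(len(categories))
    idx = {c: i for i, c in enumerate(categories)}
    for cat, w in weights.items():
        v[idx[cat]] += w
    v += noise * rng.dirichlet(np.ones(len(categories)))
    return v / v.sum()


def _sub_mass(sub: str, rng, concentration: float = 1.0) -> dict[str, float]:
    cats = [c for c in SBS96_CATEGORIES if f"[{sub}]" in c]
    w = rng.dirichlet(concentration * np.ones(len(cats)))
    return dict(zip(cats, w))


def build_sbs(rng) -> pd.DataFrame:
    sigs = {}
    # CpG-deamination-like: mass on N[C>T]G
    cpg = {c: 0.92 / 4 for c in SBS96_CATEGORIES if "[C>T]G" in c}
    sigs["SBS1"] = _mass(SBS96_CATEGORIES, cpg, 0.08, rng)
    # broad clock-like (rough enough to be separable from the others)
    rng5 = np.random.default_rng(55)
    sigs["SBS5"] = rng5.dirichlet(0.8 * np.ones(len(SBS96_CATEGORIES)))
    # C>A heavy (proofreading-deficiency-like)
    sigs["SBS10a"] = _mass(
        SBS96_CATEGORIES,
        {k: 0.9 * v for k, v in _sub_mass("C>A", rng, 0.5).items()},
        0.1, rng,
    )
    # MMR-deficiency-like pair: C>T non-CpG biased / T>C biased
    ct = {
        k: 0.85 * v
        for k, v in _sub_mass("C>T", rng, 0.7).items()
        if not k.endswith("G")
    }
    sigs["SBS15"] = _mass(SBS96_CATEGORIES, ct, 0.15, rng)
    tc = {k: 0.85 * v for k, v in _sub_mass("T>C", rng, 0.7).items()}
    sigs["SBS21"] = _mass(SBS96_CATEGORIES, tc, 0.15, rng)
    # MSI-associated / artifact-prone
    tg = {k: 0.8 * v for k, v in _sub_mass("T>G", rng, 0.4).items()}
    sigs["SBS54"] = _mass(SBS96_CATEGORIES, tg, 0.2, rng)
    df = pd.DataFrame(sigs, index=list(SBS96_CATEGORIES))
    df.index.name = "Type"
    return df


def build_id(rng) -> pd.DataFrame:
    # keep mass on bins that are placeable on a random reference:
    # 1 bp homopolymer events and short non-repeat deletions/insertions
    sigs = {}
    id1 = {
        "1:Ins:T:5": 0.30, "1:Ins:T:4": 0.25, "1:Ins:T:3": 0.15,
        "1:Ins:C:1": 0.05, "1:Ins:C:2": 0.05,
    }
    sigs["ID1"] = _mass(ID83_CATEGORIES, id1, 0.20, rng)
    id2 = {
        "1:Del:T:5": 0.30, "1:Del:T:4": 0.25, "1:Del:T:3": 0.15,
        "1:Del:C:2": 0.05, "1:Del:C:3": 0.05,
    }
    sigs["ID2"] = _mass(ID83_CATEGORIES, id2, 0.20, rng)
    id12 = {
        "2:Del:R:0": 0.25, "3:Del:R:0": 0.20, "2:Ins:R:0": 0.15,
        "4:Del:R:0": 0.10, "1:Del:C:0": 0.10,
    }
    sigs["ID12"] = _mass(ID83_CATEGORIES, id12, 0.20, rng)
    df = pd.DataFrame(sigs, index=list(ID83_CATEGORIES))
    df.index.name = "Type"
    return df


def build_bins() -> pd.DataFrame:
    rows = []
    for cat in ID83_CATEGORIES:
        size, kind, ctx, num = cat.split(":")
        if size == "1" and kind == "Del":
            desc = f"1 bp {ctx} deletion, homopolymer length {num if num != '5' else '>=6'}"
        elif size == "1":
            desc = f"1 bp {ctx} insertion, existing run length {num if num != '5' else '>=5'}"
        elif ctx == "M":
            desc = f"{size} bp deletion with {num} bp flanking microhomology"
        elif kind == "Del":
            desc = f"{size} bp deletion, {num} extra tandem copies"
        else:
            desc = f"{size} bp insertion, {num} existing tandem copies"
        rows.append((cat, desc))
    return pd.DataFrame(rows, columns=["category", "description"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20210223)
    build_sbs(rng).to_csv(OUT / "sbs96_catalog.tsv", sep="\t", float_format="%.8g")
    build_id(rng).to_csv(OUT / "id83_catalog.tsv", sep="\t", float_format="%.8g")
    build_bins().to_csv(OUT / "id83_bins.tsv", sep="\t", index=False)
    print(f"wrote catalogs to {OUT}")


if __name__ == "__main__":
    main()
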