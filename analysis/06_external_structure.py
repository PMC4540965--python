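#!/usr/bin/env python
"""Opt-in external-structure check (requires user-supplied files).

Given a real PDB structure, a Naccess .rsa accessibility file (optional;
internal Shrake-Rupley otherwise), and a column->residue mapping for a
reference alignment, count the residue pairs in which both residues are
completely buried (0% relative accessibility) and report the fraction of
those pairs closer than the contact threshold.  For a compact globular
protein the completely-buried pairs are expected to be heavily enriched in
contacts.

Example:
    python analysis/06_external_structure.py --pdb protein.pdb \
        --rsa protein.rsa --map mapping.tsv --threshold 10
"""

import argparse
import itertools

from coevotrace import structure as struct


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb", required=True)
    parser.add_argument("--rsa", default=None)
    parser.add_argument("--map", dest="mapping", default=None)
    parser.add_argument("--chain", default=None)
    parser.add_argument("--threshold", type=float, default=10.0)
    args = parser.parse_args()

    context = struct.read_pdb(args.pdb, chain=args.chain)
    if args.rsa:
        struct.attach_rsa(context, struct.read_rsa(args.rsa))
    else:
        context.rel_acc = struct.compute_sasa(context)
    if args.mapping:
        context.col_to_res = struct.read_mapping(args.mapping)
        residues = [context.col_to_res[c] for c in context.mapped_columns()]
    else:
        residues = sorted(context.coords, key=lambda k: (k.chain, k.resnum, k.icode))

    buried = [
        r for r in residues
        if r in context.rel_acc
        and struct.burial_class(r, context) == "completely_buried"
    ]
    pairs = list(itertools.combinations(buried, 2))
    print(f"{len(buried)} completely buried residues -> {len(pairs)} pairs")
    if not pairs:
        return
    close = sum(
        struct.min_heavy_atom_distance(context, a, b) < args.threshold
        for a, b in pairs
    )
    print(
        f"{close}/{len(pairs)} buried pairs ({100 * close / len(pairs):.1f}%) "
        f"are closer than {args.threshold} A"
    )


if __name__ == "__main__":
    main()
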