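#!/usr/bin/env python
"""Recompute every derived reference quantity and report agreement.

Runs the package's conversion, reduction, regression, kinetic-fit and
fold-change routines on the bundled printed inputs and prints a pass/fail
table.  (The single expected failure is one conversion cell whose printed
concentration was rounded before printing.)  Writes the table under
results/05_reference_verification/.
"""

from pathlib import Path

from sonogold import io as sgio
from sonogold.reference import verify_reference_values

OUT = Path("results/05_reference_verification")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = verify_reference_values()
    sgio.write_table(table, OUT / "reference_verification.tsv")
    print(table.to_string(index=False))
    print(f"\n{int(table.passed.sum())}/{len(table)} checks passed "
          f"(table under {OUT}/)")


if __name__ == "__main__":
    main()
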