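# Methods

This note documents the models, numerical choices and limitations
behind lapkit, in the order a protocol flows through the toolkit.

## Protocol names and script structure

A protocol identifier is four hyphen-separated fields: the fixed
repository token `LAP`, an alphanumeric CamelCase description, a
platform tag, and a semantic version (`major.minor.patch`, integer
parts).  Because the hyphen is the delimiter, no field may contain one;
parsing strips a recognized trailing file extension (`.py`, `.xlsx`,
…) first.  Parse and format are exact inverses on the valid-name set,
which the suite checks as a property.

A conforming automation script declares exactly three top-level
sections — *Classes* (user-variable handling), *Functions* (shared
liquid-handling routines) and *Body* (the protocol-specific sequence) —
in that order.  `validate_lap_structure` enforces the count, the names
and the order; missing, extra and permuted sections are distinct
errors.

## Customizable Variable Files

The CVF is a two-column model — section → ordered (variable, value)
pairs, values kept as raw strings until validation — realized in four
dialects:

| dialect | carrier |
|---|---|
| `xlsx` | one worksheet per section, columns `Variable`, `Value`[, `Value 2`, …] |
| `csv-bundle` | a directory, one `<Section>.csv` per section, same columns |
| `json` | one object per section, variable → string or array |
| `xml` | `<section name=…><variable name=…>` elements, repeated `<value>` children for lists |

All four carry the same information, and any document written to one
dialect and re-read compares equal to the original — the
dialect-independence property the suite tests.  Multi-valued variables
(e.g. a media list) are string lists; a single cell stays a scalar
string.  Variable names are case-sensitive exact tokens and blank cells
mean *absent*, never zero: silent coercion of an empty cell to 0 µL is
exactly the class of error the validator exists to catch.

Validation is two-phase and total.  Phase one types each declared
variable (decimal numbers only — thousands separators are rejected;
booleans as case-insensitive True/False) and checks bounds and allowed
choices.  Phase two runs cross-variable rules: at least one pipette
mounted; every mounted pipette has its tip-rack name (`pipR` ⇒
`APINameTipR`, `pipL` ⇒ `APINameTipL`); labware names resolve in the
catalog; and the summed per-well `volume_*` variables fit the
destination well maximum.  Every problem becomes a report issue —
nothing raises, nothing stops at the first error — and a typed
`UserVariables` is produced only from a clean report.  Undeclared
variables are warnings, not errors, so a CVF written for a newer
protocol revision still validates.

## Labware and tube geometry

The built-in catalog defines the standard SBS 96-well microplate (8×12,
200 µL wells), a deep-well variant, a 12-channel reservoir (treated as
a row of very large wells under the same overfill rule), 96-tip racks
for the three supported pipette models (1–20, 20–300, 100–1000 µL),
and 15 mL / 50 mL conical-tube racks.  Well ids are letter-row +
1-based column (`A1` top-left); deck slots are numbered 1–11 and
auto-assigned labware takes the lowest free slot, tip racks first —
a fixed policy chosen for determinism.

A conical tube is an inverted cone of height *h*c and junction radius
*r* under a cylinder of height *h*cyl, with the mm³ = µL identity:

    V(h) = (π/3)(r·h/h_c)²·h              h ≤ h_c
    V(h) = V(h_c) + π·r²·(h − h_c)        h > h_c

V is continuous and strictly increasing, and inverts in closed form
(cube root on the cone branch, linear on the cylinder branch).  The
suite checks mutual inversion to 1e-6 relative over a 10 000-point grid
spanning both branches and the junction, and validates the closed form
against a trapezoid-rule quadrature of the radius profile.

Default 15 mL geometry: *r* = 7.5 mm, *h*c = 22 mm, *h*cyl = 95 mm,
nominal capacity 15 000 µL, dead volume 1 000 µL.  These are nominal,
catalog-configurable constants of this toolkit, not vendor-certified
dimensions; the construction-time invariant `V(h_c + h_cyl) ≥ nominal
capacity` rejects geometries that cannot physically hold their label.

## Planning

**Pipette selection.**  For a pipette with range [min, max], the only
candidate movement count is k = ⌈V/max⌉: any larger k raises the
k·min lower bound as well, so if k·min > V no count works.  Chunking
fills k−1 maxima plus the remainder; a remainder below min is repaired
by splitting the last two chunks evenly, and — when the pair split
itself leaves the range (possible for narrow [min, max] bands) — by an
even split over all k chunks, which is always in range when k is
feasible (min ≤ V/k ≤ max).  Ties between pipettes needing equal
movements prefer the one whose maximum is closest to the per-movement
volume (less oversized, hence more precise), then the right mount.
The suite verifies movement counts against a brute-force oracle that
tries every chunk count per pipette.

**Tube allocation.**  Usable volume per tube is `nominal capacity ×
0.9 − dead volume` (the 0.9 fill limit is a configurable safety margin
against filling to the brim).  Tube count is ceiling division of the
reagent total; fills spread the total plus one dead volume per tube
evenly, so no tube is fuller than another by more than rounding.

**Reagent totals.**  `samples × per-sample volume × (1 + excess)`.
The excess fraction defaults to 0 for plain transfers and 0.1 for
master-mix preparation — the common bench practice of making 10 % extra
mix so the last reaction is never short — and is CVF-configurable.

Plans are deterministic (identical inputs give byte-identical JSON) and
serializable; plan JSON is the interchange format between planning and
execution, and concatenating plans (with compatible deck layouts) is
the unit of workflow composition.  Protocol generators accept an
`occupied` base layout so a downstream plan reuses the tip racks
already on deck and takes fresh slots for its own labware.

## Virtual execution

Every primitive validates *all* its preconditions before mutating a
copied state, so a failing step is an exact no-op — the atomicity the
fault-injection suite checks.  Enforced invariants: no well below 0 µL
or above its maximum at any intermediate point; tube wells additionally
never below dead volume; a pipette must carry a tip and be empty to
aspirate, hold enough to dispense, and never exceeds its [min, max] per
movement; tips are decremented per pick and a fresh rack of the bound
type is auto-loaded into the lowest free slot when all racks run dry
(`DeckFull` when none is free).

Z-tracked distribution batches consecutive dispenses greedily (no
reordering — user order is meaningful) up to the pipette maximum, and
computes each aspiration height as `height_from_volume(current tube
volume) − 10 mm`, clamped at 1 mm above the apex.  The 10 mm submersion
offset and 1 mm clearance are this toolkit's own defaults — deep enough
that the tip stays wetted as the level falls during the aspiration,
shallow enough to minimize tip submersion; both are module constants.
The operation is bound to the 15 mL geometry because the offset
calibration does not transfer to wider tubes: a 50 mL tube drops its
level ~3.2× more slowly per µL, so the same offset would submerge the
tip excessively; any other nominal capacity raises
`UnsupportedLabware`.

Aspiration heights appear in the action log, whose entries carry
pre/post digests (order-stable SHA-256 over sorted (slot, well, volume)
triples plus tip and pipette state) — two runs agree iff their digests
agree, which is how the concatenation-equals-sequential-execution
property is tested.

## Reference protocols

*Inoculation*: each of n samples × m media gets one destination well;
media are distributed from conical tubes with z-tracking (one tip per
medium), then inoculum is added from each sample's source well with a
fresh tip per transfer (cross-contamination discipline).  An empty
media list yields an empty plan with a warning comment rather than an
error.  *Consolidation*: sample i moves from source plate ⌊i/96⌋, well
i mod 96 (column-major) to destination well i; more than 96 samples is
refused.  *PCR mix*: components are pooled pro rata into the mix
tube(s), the mix is distributed per reaction, template added per well;
the temperature profile is emitted as a YAML schedule only — no
thermocycler control.  *Counter selection* is defined here as the
conjunction of two directional thresholds on two distinct per-sample
measurements (≥ or ≤ each); samples missing a measurement are an error,
output is in sorted id order, and the selected ids are exactly the
sample-name list consolidation accepts.

## Synthetic fixtures

The fixture generator emulates the variable files a lab would fill in:
seeded-random but realistic sample counts (4–96), media panels drawn
from common growth media, per-well volumes within the 96-well plate's
200 µL working range, and a standard two-pipette deck (p20 left, p300
right).  Broken variants each contain exactly one violation (missing
tip rack, unknown pipette model, non-numeric count, zero samples, no
pipettes, overfilled well, unknown labware, negative volume, bad
comparator) so validator tests can assert one diagnosis per file.
What the fixtures do *not* emulate: real vendor labware dimensions,
multi-channel pipettes, evaporation, viscosity and timing — green tests
certify the accounting and the format contracts, not the physical
calibration of any particular robot.

## Problem sizes

The default suite runs 200 seeded random protocol plans for the
conservation property, 1 000 random cases against the pipette
brute-force oracle, and 10 000 grid points for the geometry inversion
— sizes at which every property has either a counterexample or dense
coverage of the branch structure, while the whole suite stays in the
seconds range.  `scripts/acceptance.py` re-measures the same quantities
from scratch at the same sizes.

## Known limitations

No 8-channel pipetting, no travel-path or collision modeling, no
flow-rate/viscosity physics, no evaporation, no thermocycler driver,
and no support for vendor-native protocol file formats.  Volumes are
floats in µL with 1e-9-µL comparison slack; totals in realistic plans
stay well below the scale where float error could reach a pipetting
tolerance.
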