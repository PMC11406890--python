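# Toy JSON reconstruction dialect

A compact, human-readable serialization of a taxon metabolic reconstruction,
used for fixtures and generated scenarios so that tests need no SBML reader.
SBML Level 3 (with fbc flux bounds) is supported in parallel by
`weanflux.recon` for interoperability.

## Top-level object

| key           | type   | meaning                                    |
|---------------|--------|--------------------------------------------|
| `taxon_id`    | string | genus (or strain) identifier               |
| `metabolites` | array  | metabolite records (see below)             |
| `reactions`   | array  | reaction records (see below)               |

## Metabolite record

| key           | type   | meaning                                                        |
|---------------|--------|----------------------------------------------------------------|
| `id`          | string | unique within the reconstruction                               |
| `name`        | string | optional display name                                          |
| `compartment` | string | `"lumen"` (shared), `"external"` (boundary), or the taxon id   |

## Reaction record

| key      | type   | meaning                                                      |
|----------|--------|--------------------------------------------------------------|
| `id`     | string | unique within the reconstruction                             |
| `stoich` | object | metabolite id → signed coefficient                           |
| `lb`     | number | lower flux bound, mmol/(gDW·h); default −1000 if absent      |
| `ub`     | number | upper flux bound, mmol/(gDW·h); default +1000 if absent      |
| `kind`   | string | `"internal"`, `"exchange"`, or `"biomass"`                   |

Constraints enforced on read: exactly one `biomass` reaction; every `stoich`
key resolves to a declared metabolite; `lb <= ub`; an `exchange` reaction
touches exactly one lumen/external metabolite and non-exchange reactions
touch none. Sign convention: positive exchange flux is secretion into the
lumen, negative is uptake.

## Example

```json
{
 "taxon_id": "Bifidobacterium",
 "metabolites": [
  {"id": "hmo", "name": "", "compartment": "lumen"},
  {"id": "hmo_in", "name": "", "compartment": "Bifidobacterium"},
  {"id": "biomass_pool", "name": "", "compartment": "Bifidobacterium"}
 ],
 "reactions": [
  {"id": "EX_hmo", "stoich": {"hmo_in": -1.0, "hmo": 1.0},
   "lb": -1000.0, "ub": 0.0, "kind": "exchange"},
  {"id": "ferment_hmo", "stoich": {"hmo_in": -1.0, "biomass_pool": 0.05},
   "lb": 0.0, "ub": 1000.0, "kind": "internal"},
  {"id": "biomass", "stoich": {"biomass_pool": -1.0},
   "lb": 0.0, "ub": 1000.0, "kind": "biomass"}
 ]
}
```
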