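{
  "characters": [
    {
      "id": "character:color",
      "states": [
        {
          "id": "state:blue",
          "title": "Blue"
        },
        {
          "id": "state:red",
          "title": "Red"
        }
      ],
      "title": "Color"
    },
    {
      "id": "character:size",
      "states": [
        {
          "id": "state:small",
          "title": "Small"
        },
        {
          "id": "state:large",
          "title": "Large"
        }
      ],
      "title": "Size"
    }
  ],
  "created": "2022-12-01",
  "creator": "person:example",
  "identifier": "urn:clavis:example:fig2",
  "language": [
    "en"
  ],
  "lastModified": "2022-12-01",
  "license": "https://creativecommons.org/licenses/by/4.0/",
  "persons": [
    {
      "id": "person:example",
      "name": "Example Author"
    }
  ],
  "schema": "https://clavis.no/schema/1.0",
  "statements": [
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:f1",
      "taxon": "taxon:t1",
      "value": "state:blue"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:f2",
      "taxon": "taxon:t2",
      "value": "state:blue"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:f3",
      "taxon": "taxon:t3",
      "value": "state:red"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:f4",
      "taxon": "taxon:t4",
      "value": "state:red"
    },
    {
      "character": "character:size",
      "frequency": 1.0,
      "id": "statement:f5",
      "taxon": "taxon:t1",
      "value": "state:small"
    },
    {
      "character": "character:size",
      "frequency": 1.0,
      "id": "statement:f6",
      "taxon": "taxon:t2",
      "value": "state:large"
    },
    {
      "character": "character:size",
      "frequency": 1.0,
      "id": "statement:f7",
      "taxon": "taxon:t3",
      "value": "state:small"
    }
  ],
  "taxa": [
    {
      "id": "taxon:t1",
      "scientificName": "Taxus exemplaris 1"
    },
    {
      "id": "taxon:t2",
      "scientificName": "Taxus exemplaris 2"
    },
    {
      "id": "taxon:t3",
      "scientificName": "Taxus exemplaris 3"
    },
    {
      "id": "taxon:t4",
      "scientificName": "Taxus exemplaris 4"
    }
  ],
  "title": "Four taxa, two characters"
}
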