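{
  "characters": [
    {
      "id": "character:body",
      "states": [
        {
          "id": "state:elongated",
          "title": "Elongated"
        },
        {
          "id": "state:round",
          "title": "Round"
        }
      ],
      "title": "Body shape"
    },
    {
      "id": "character:antennae",
      "states": [
        {
          "id": "state:straight",
          "title": "Straight"
        },
        {
          "id": "state:curved",
          "title": "Curved"
        },
        {
          "id": "state:clubbed",
          "title": "Clubbed"
        }
      ],
      "title": "Antenna shape"
    },
    {
      "id": "character:sheen",
      "states": [
        {
          "id": "state:shiny",
          "title": "Shiny"
        },
        {
          "id": "state:dull",
          "title": "Dull"
        }
      ],
      "title": "Surface sheen"
    },
    {
      "id": "character:color",
      "states": [
        {
          "id": "state:col_red",
          "title": "Red"
        },
        {
          "id": "state:col_green",
          "title": "Green"
        },
        {
          "id": "state:col_blue",
          "title": "Blue"
        }
      ],
      "title": "Colors",
      "type": "nonExclusive"
    },
    {
      "id": "character:ornament",
      "states": [
        {
          "id": "state:orn_present",
          "title": "Present"
        },
        {
          "id": "state:orn_absent",
          "title": "Absent"
        }
      ],
      "title": "Frontal ornament"
    }
  ],
  "created": "2022-12-01",
  "creator": "person:example",
  "identifier": "urn:clavis:example:clavidae",
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
      "character": "character:body",
      "frequency": 1.0,
      "id": "statement:cl01",
      "taxon": "taxon:clavidae",
      "value": "state:elongated"
    },
    {
      "character": "character:body",
      "frequency": 0.0,
      "id": "statement:cl02",
      "taxon": "taxon:clavidae",
      "value": "state:round"
    },
    {
      "character": "character:antennae",
      "frequency": 1.0,
      "id": "statement:cl03",
      "taxon": "taxon:clavis",
      "value": "state:straight"
    },
    {
      "character": "character:antennae",
      "frequency": 1.0,
      "id": "statement:cl04",
      "taxon": "taxon:clavella",
      "value": "state:curved"
    },
    {
      "character": "character:antennae",
      "frequency": 1.0,
      "id": "statement:cl05",
      "taxon": "taxon:clavissima",
      "value": "state:clubbed"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl06",
      "taxon": "taxon:clavis_default",
      "value": "state:dull"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl07",
      "taxon": "taxon:clavis_shiny",
      "value": "state:shiny"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl08",
      "taxon": "taxon:clavella_default",
      "value": "state:dull"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl09",
      "taxon": "taxon:clavella_shiny",
      "value": "state:shiny"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl10",
      "taxon": "taxon:clavissima_default",
      "value": "state:dull"
    },
    {
      "character": "character:sheen",
      "frequency": 1.0,
      "id": "statement:cl11",
      "taxon": "taxon:clavissima_shiny",
      "value": "state:shiny"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:cl12",
      "taxon": "taxon:clavis",
      "value": "state:col_red"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:cl13",
      "taxon": "taxon:clavis",
      "value": "state:col_green"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:cl14",
      "taxon": "taxon:clavella",
      "value": "state:col_red"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:cl15",
      "taxon": "taxon:clavissima",
      "value": "state:col_green"
    },
    {
      "character": "character:color",
      "frequency": 1.0,
      "id": "statement:cl16",
      "taxon": "taxon:clavissima",
      "value": "state:col_blue"
    },
    {
      "character": "character:color",
      "frequency": 0.0,
      "id": "statement:cl17",
      "taxon": "taxon:clavissima",
      "value": "state:col_red"
    },
    {
      "character": "character:ornament",
      "frequency": 1.0,
      "id": "statement:cl18",
      "taxon": "taxon:clavissima_female",
      "value": "state:orn_present"
    },
    {
      "character": "character:ornament",
      "frequency": 1.0,
      "id": "statement:cl19",
      "taxon": "taxon:clavissima_male",
      "value": "state:orn_absent"
    }
  ],
  "taxa": [
    {
      "children": [
        {
          "children": [
            {
              "id": "taxon:clavis_default",
              "label": ""
            },
            {
              "id": "taxon:clavis_shiny",
              "label": "Shiny"
            }
          ],
          "id": "taxon:clavis",
          "scientificName": "Clavis"
        },
        {
          "children": [
            {
              "id": "taxon:clavella_default",
              "label": ""
            },
            {
              "id": "taxon:clavella_shiny",
              "label": "Shiny"
            }
          ],
          "id": "taxon:clavella",
          "scientificName": "Clavella"
        },
        {
          "children": [
            {
              "children": [
                {
                  "id": "taxon:clavissima_female",
                  "label": "♀"
                },
                {
                  "id": "taxon:clavissima_male",
                  "label": "♂"
                }
              ],
              "id": "taxon:clavissima_default",
              "isEndpoint": true,
              "label": ""
            },
            {
              "id": "taxon:clavissima_shiny",
              "label": "Shiny"
            }
          ],
          "id": "taxon:clavissima",
          "scientificName": "Clavissima"
        }
      ],
      "id": "taxon:clavidae",
      "scientificName": "Clavidae"
    }
  ],
  "title": "Key to the Clavidae"
}
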