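# Simple Darwin Core term names (flat term list).
# Source: http://rs.tdwg.org/dwc/terms/simple/ — transcribed 2023-09-18.
# One term per line; lines starting with '#' are comments.
type
modified
language
license
rightsHolder
accessRights
bibliographicCitation
references
institutionID
collectionID
datasetID
institutionCode
collectionCode
datasetName
ownerInstitutionCode
basisOfRecord
informationWithheld
dataGeneralizations
dynamicProperties
occurrenceID
catalogNumber
recordNumber
recordedBy
recordedByID
individualCount
organismQuantity
organismQuantityType
sex
lifeStage
reproductiveCondition
behavior
establishmentMeans
degreeOfEstablishment
pathway
georeferenceVerificationStatus
occurrenceStatus
preparations
disposition
associatedMedia
associatedOccurrences
associatedReferences
associatedSequences
associatedTaxa
otherCatalogNumbers
occurrenceRemarks
organismID
organismName
organismScope
associatedOrganisms
previousIdentifications
organismRemarks
materialSampleID
eventID
parentEventID
fieldNumber
eventDate
eventTime
startDayOfYear
endDayOfYear
year
month
day
verbatimEventDate
habitat
samplingProtocol
sampleSizeValue
sampleSizeUnit
samplingEffort
fieldNotes
eventRemarks
locationID
higherGeographyID
higherGeography
continent
waterBody
islandGroup
island
country
countryCode
stateProvince
county
municipality
locality
verbatimLocality
minimumElevationInMeters
maximumElevationInMeters
verbatimElevation
verticalDatum
minimumDepthInMeters
maximumDepthInMeters
verbatimDepth
minimumDistanceAboveSurfaceInMeters
maximumDistanceAboveSurfaceInMeters
locationAccordingTo
locationRemarks
decimalLatitude
decimalLongitude
geodeticDatum
coordinateUncertaintyInMeters
coordinatePrecision
pointRadiusSpatialFit
verbatimCoordinates
verbatimLatitude
verbatimLongitude
verbatimCoordinateSystem
verbatimSRS
footprintWKT
footprintSRS
footprintSpatialFit
georeferencedBy
georeferencedDate
georeferenceProtocol
georeferenceSources
georeferenceRemarks
geologicalContextID
earliestEonOrLowestEonothem
latestEonOrHighestEonothem
earliestEraOrLowestErathem
latestEraOrHighestErathem
earliestPeriodOrLowestSystem
latestPeriodOrHighestSystem
earliestEpochOrLowestSeries
latestEpochOrHighestSeries
earliestAgeOrLowestStage
latestAgeOrHighestStage
lowestBiostratigraphicZone
highestBiostratigraphicZone
lithostratigraphicTerms
group
formation
member
bed
identificationID
verbatimIdentification
identificationQualifier
typeStatus
identifiedBy
identifiedByID
dateIdentified
identificationReferences
identificationVerificationStatus
identificationRemarks
taxonID
scientificNameID
acceptedNameUsageID
parentNameUsageID
originalNameUsageID
nameAccordingToID
namePublishedInID
taxonConceptID
scientificName
acceptedNameUsage
parentNameUsage
originalNameUsage
nameAccordingTo
namePublishedIn
namePublishedInYear
higherClassification
kingdom
phylum
class
order
family
subfamily
genus
genericName
subgenus
infragenericEpithet
specificEpithet
infraspecificEpithet
cultivarEpithet
taxonRank
verbatimTaxonRank
scientificNameAuthorship
vernacularName
nomenclaturalCode
taxonomicStatus
nomenclaturalStatus
taxonRemarks
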